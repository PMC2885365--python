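"""End-to-end convenience drivers gluing the pipeline stages together."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from . import annotate, discovery, families_clusters, preprocess
from .formats_io import GeneModel, ReferenceSet, TagFileRecord

ELIMINATION_ORDER = ("mature_miRNA", "ncRNA", "rRNA_mRNA", "exon")


@dataclass
class SampleResult:
    sample: str
    tags: list[preprocess.SmallRNATag]
    stats: dict
    records: list[annotate.AnnotationRecord]
    unmatched: list[preprocess.SmallRNATag]
    genomic_hits: list[annotate.GenomicHit]
    composition: dict[str, float]
    profile: pd.DataFrame
    candidates: list[discovery.PrecursorCandidate] = field(default_factory=list)
    families: list[families_clusters.MiRNAFamily] = field(default_factory=list)


def run_sample(
    sample: str,
    tag_records: Sequence[TagFileRecord] | None = None,
    raw_reads: Sequence[str] | None = None,
    reference_sets: Mapping[str, ReferenceSet] | None = None,
    genome: Mapping[str, str] | None = None,
    gene_model: GeneModel | None = None,
    adapter: preprocess.AdapterSpec = preprocess.AdapterSpec(),
    min_len: int = preprocess.DEFAULT_MIN_LEN,
    fold_params: discovery.FoldParams | None = None,
    flank: int = discovery.DEFAULT_FLANK,
    discover: bool = True,
) -> SampleResult:
    """Run one sample through trim/collapse, elimination, genome mapping,
    known-miRNA profiling, and (optionally) novel-candidate discovery."""
    from .expression import known_mirna_profile

    tags, stats = preprocess.preprocess_reads(
        raw=raw_reads, tag_records=tag_records, adapter=adapter,
        min_len=min_len, sample=sample,
    )
    ordered_refs = [
        reference_sets[cat] for cat in ELIMINATION_ORDER
        if reference_sets and cat in reference_sets
    ]
    records, unmatched, _ = annotate.run_elimination(tags, ordered_refs)
    genomic_hits: list[annotate.GenomicHit] = []
    if genome is not None and gene_model is not None:
        genomic_hits = annotate.map_unmatched_to_genome(unmatched, genome, gene_model)
    labels = {h.tag_id: h.label for h in genomic_hits}
    composition = annotate.category_composition(records, tags, genomic_labels=labels)
    profile = known_mirna_profile(records, tags)
    result = SampleResult(
        sample=sample, tags=tags, stats=stats, records=records,
        unmatched=unmatched, genomic_hits=genomic_hits,
        composition=composition, profile=profile,
    )
    if discover and genome is not None and genomic_hits:
        freqs = {t.id: t.frequency for t in tags}
        result.candidates = discovery.discover_candidates(
            genomic_hits, genome, flank=flank, params=fold_params,
            frequencies=freqs, sample=sample,
        )
        result.families = families_clusters.group_by_precursor(result.candidates)
        families_clusters.assign_names(result.families)
    return result
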