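"""Sequential annotation cascade for small-RNA tags.

Tags are matched against an ordered list of reference sets (known mature
miRNAs first, then other ncRNAs, rRNA/mRNA, exons) with an ungapped
substitution-only matcher allowing up to two mismatches. Every tag gets the
category of the FIRST set it hits and is removed before the next round; the
survivors are mapped exactly to the genome and labeled intergenic/intronic.

Completeness of the seeded matcher follows from the pigeonhole principle:
a tag split into (max_mismatches + 1) segments must contain at least one
exact segment, so seeding each segment's k-mer prefix and verifying the full
Hamming distance enumerates every hit.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .formats_io import GeneModel, ReferenceSet, reverse_complement
from .preprocess import SmallRNATag

UNANNOTATED = "unannotated"


@dataclass(frozen=True)
class MatchHit:
    tag_id: int
    reference_id: str
    offset: int
    mismatches: int
    strand: str = "+"


@dataclass
class AnnotationRecord:
    tag_id: int
    category: str
    best_hit: MatchHit | None = None


def _hamming_leq(a: str, b: str, budget: int) -> int:
    """Mismatch count of equal-length strings, or -1 once it exceeds budget.

    N never matches anything, including another N.
    """
    mm = 0
    for x, y in zip(a, b):
        if x != y or x == "N":
            mm += 1
            if mm > budget:
                return -1
    return mm


class KmerIndex:
    """Exact k-mer substring index over a reference set."""

    def __init__(self, reference_set: ReferenceSet, k: int):
        if k < 1:
            raise ValueError("k must be >= 1")
        self.k = k
        self.reference_set = reference_set
        self.sequences: dict[str, str] = dict(reference_set.records)
        self.postings: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for ref_id, seq in reference_set.records:
            if len(seq) < k:
                warnings.warn(
                    f"reference {ref_id!r} shorter than k={k}; indexed at full length"
                )
                self.postings[seq].append((ref_id, 0))
                continue
            for i in range(len(seq) - k + 1):
                self.postings[seq[i : i + k]].append((ref_id, i))

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        return self.postings.get(kmer, [])

    def n_postings(self) -> int:
        return sum(len(v) for v in self.postings.values())


def build_kmer_index(reference_set: ReferenceSet, k: int) -> KmerIndex:
    return KmerIndex(reference_set, k)


def choose_k(min_tag_length: int, max_mismatches: int = 2, cap: int = 8) -> int:
    """Seed length keeping the pigeonhole completeness guarantee."""
    return max(1, min(cap, min_tag_length // (max_mismatches + 1)))


def mismatch_match(
    tag_seq: str, index: KmerIndex, max_mismatches: int = 2
) -> list[MatchHit]:
    """All ungapped full-tag alignments with Hamming distance <= max_mismatches.

    The tag is split into (max_mismatches + 1) segments; the k-prefix of each
    segment is looked up exactly and every candidate placement is verified.
    """
    n = len(tag_seq)
    k = index.k
    n_seg = max_mismatches + 1
    if n < n_seg * k:
        # tag too short for the pigeonhole split at this k: verify directly
        hits = []
        for ref_id, ref_seq in index.sequences.items():
            for off in range(len(ref_seq) - n + 1):
                mm = _hamming_leq(tag_seq, ref_seq[off : off + n], max_mismatches)
                if mm >= 0:
                    hits.append(MatchHit(-1, ref_id, off, mm))
        return hits

    seg_len = n // n_seg
    seen: set[tuple[str, int]] = set()
    hits: list[MatchHit] = []
    for s in range(n_seg):
        seg_start = s * seg_len
        kmer = tag_seq[seg_start : seg_start + k]
        for ref_id, pos in index.lookup(kmer):
            off = pos - seg_start
            if off < 0:
                continue
            ref_seq = index.sequences[ref_id]
            if off + n > len(ref_seq):
                continue
            if (ref_id, off) in seen:
                continue
            seen.add((ref_id, off))
            mm = _hamming_leq(tag_seq, ref_seq[off : off + n], max_mismatches)
            if mm >= 0:
                hits.append(MatchHit(-1, ref_id, off, mm))
    hits.sort(key=lambda h: (h.mismatches, h.reference_id, h.offset))
    return hits


def run_elimination(
    tags: Sequence[SmallRNATag],
    reference_sets: Sequence[ReferenceSet],
    max_mismatches: int = 2,
) -> tuple[list[AnnotationRecord], list[SmallRNATag], list[MatchHit]]:
    """Assign each tag the category of the first reference set it hits.

    Returns (annotation records, unmatched tag pool, multi-mapping report).
    The report lists every hit of each tag within its winning stage; the
    tag's frequency is never split across references.
    """
    records: dict[int, AnnotationRecord] = {}
    multimap: list[MatchHit] = []
    pool = list(tags)
    min_len = min((t.length for t in pool), default=0)
    for ref_set in reference_sets:
        if not ref_set.records:
            warnings.warn(f"empty reference set {ref_set.name!r}; stage skipped")
            continue
        if not pool:
            break
        k = choose_k(min_len, max_mismatches)
        index = build_kmer_index(ref_set, k)
        survivors = []
        for tag in pool:
            hits = mismatch_match(tag.sequence, index, max_mismatches)
            if not hits:
                survivors.append(tag)
                continue
            best = min(hits, key=lambda h: (h.mismatches, h.reference_id, h.offset))
            best = MatchHit(tag.id, best.reference_id, best.offset, best.mismatches)
            records[tag.id] = AnnotationRecord(tag.id, ref_set.category, best)
            if len(hits) > 1:
                multimap.extend(
                    MatchHit(tag.id, h.reference_id, h.offset, h.mismatches)
                    for h in hits
                )
        pool = survivors
    for tag in pool:
        records[tag.id] = AnnotationRecord(tag.id, UNANNOTATED, None)
    ordered = [records[t.id] for t in tags]
    return ordered, pool, multimap


@dataclass(frozen=True)
class GenomicHit:
    """Exact genomic placement of an unannotated tag."""

    tag_id: int
    chrom: str
    start: int
    end: int
    strand: str
    label: str  # intergenic or intronic


def map_unmatched_to_genome(
    pool: Sequence[SmallRNATag],
    genome: Mapping[str, str],
    gene_model: GeneModel,
) -> list[GenomicHit]:
    """Exact-match leftover tags to both genome strands.

    Hits fully inside an intron are intronic; hits outside all genes are
    intergenic; anything touching an exon or a gene boundary is discarded
    (those reads were already absorbed by the cascade's exon stage).
    """
    hits: list[GenomicHit] = []
    for tag in pool:
        for strand, query in (("+", tag.sequence), ("-", reverse_complement(tag.sequence))):
            for chrom, chrom_seq in genome.items():
                pos = chrom_seq.find(query)
                while pos >= 0:
                    label = gene_model.classify(chrom, pos, pos + len(query))
                    if label in ("intergenic", "intronic"):
                        hits.append(
                            GenomicHit(tag.id, chrom, pos, pos + len(query), strand, label)
                        )
                    pos = chrom_seq.find(query, pos + 1)
    return hits


def category_composition(
    records: Sequence[AnnotationRecord],
    tags: Sequence[SmallRNATag],
    genomic_labels: Mapping[int, str] | None = None,
) -> dict[str, float]:
    """Frequency-weighted category percentages (sum to 100).

    genomic_labels optionally refines unannotated tags into
    intergenic/intronic from their genomic hits.
    """
    freq_by_id = {t.id: t.frequency for t in tags}
    totals: dict[str, float] = defaultdict(float)
    for rec in records:
        cat = rec.category
        if cat == UNANNOTATED and genomic_labels and rec.tag_id in genomic_labels:
            cat = genomic_labels[rec.tag_id]
        totals[cat] += freq_by_id[rec.tag_id]
    grand = sum(totals.values())
    if grand == 0:
        return {}
    return {cat: 100.0 * f / grand for cat, f in totals.items()}
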