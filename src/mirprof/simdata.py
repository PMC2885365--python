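"""Synthetic fixtures with ground truth for every pipeline stage.

The generator emulates the study conditions of a small-RNA deep-sequencing
experiment: a toy genome with planted perfect-stem hairpins in intergenic
and intronic space, decoy RNA classes registered in matching reference sets
so the elimination cascade has true hits at every stage, delivered reads of
33/35 nt carrying a 3' adapter remnant, species abundances spanning orders
of magnitude (singletons included), and count matrices with optional
planted fold changes for differential-expression calibration.

It does NOT model sequencing errors, quality scores, or bulged precursor
stems (a bulge-rate option perturbs stems for robustness checks).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .formats_io import (
    Gene,
    GeneModel,
    GenomeRegion,
    ReferenceSet,
    TagFileRecord,
    reverse_complement,
)
from .preprocess import DEFAULT_ADAPTER

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    seed: int = 0
    genome_length: int = 60_000
    n_genes: int = 4
    exon_length: int = 400
    intron_length: int = 2_000
    exons_per_gene: int = 3
    n_hairpins: int = 20
    stem_length: int = 30
    loop_length: int = 8
    mature_length: int = 22
    n_loop_decoys: int = 5
    decoy_loop_length: int = 30
    decoy_stem_length: int = 20
    n_known_mirnas: int = 50
    n_decoys_per_category: int = 30
    read_lengths: tuple[int, int] = (33, 35)
    species_length_range: tuple[int, int] = (18, 30)
    adapter: str = DEFAULT_ADAPTER
    # log-uniform abundance bounds
    mature_abundance: tuple[float, float] = (50.0, 3000.0)
    star_abundance: tuple[float, float] = (1.0, 50.0)
    max_isomirs: int = 3
    star_probability: float = 0.6
    bulge_rate: float = 0.0


@dataclass
class PlantedHairpin:
    hairpin_id: str
    locus: GenomeRegion  # precursor span (stem-loop only, no flanks)
    placement: str  # intergenic or intronic
    five_arm: tuple[int, int]  # genomic coordinates
    three_arm: tuple[int, int]
    mature_arm: str  # five_prime or three_prime
    is_loop_decoy: bool = False
    # species planted for this hairpin: (role, sequence, count)
    species: list[tuple[str, str, int]] = field(default_factory=list)


@dataclass
class SimTruth:
    hairpins: list[PlantedHairpin]
    known_counts: dict[str, int]  # known miRNA id -> planted count
    decoy_counts: dict[str, int]  # category -> total planted frequency
    species_counts: dict[str, int]  # trimmed species sequence -> true count


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def _log_uniform_count(rng: np.random.Generator, lo: float, hi: float) -> int:
    return max(1, int(round(np.exp(rng.uniform(np.log(lo), np.log(hi))))))


def _build_hairpin(
    rng: np.random.Generator, stem: int, loop: int, bulge_rate: float
) -> str:
    left = _random_seq(rng, stem)
    loop_seq = _random_seq(rng, loop)
    right = reverse_complement(left)
    if bulge_rate > 0:
        right = "".join(
            b if rng.random() > bulge_rate else str(rng.choice(_BASES))
            for b in right
        )
    return left + loop_seq + right


def make_toy_genome(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, str], GeneModel, dict[str, ReferenceSet], SimTruth]:
    """Toy genome, gene model, reference sets, and ground truth.

    Plants perfect-stem hairpins alternating between intergenic and intronic
    space, large-loop decoy hairpins whose read sits in the loop, and decoy
    sequence classes (known miRNAs, ncRNA, rRNA/mRNA, exons) registered in
    reference sets for the elimination cascade. Placement retries up to a
    limit before raising.
    """
    rng = rng or np.random.default_rng(config.seed)
    chrom = "chr1"
    genome_arr = rng.choice(_BASES, size=config.genome_length)

    # --- gene model: evenly spaced genes with alternating exons/introns
    genes = []
    gene_len = config.exons_per_gene * config.exon_length + (
        config.exons_per_gene - 1
    ) * config.intron_length
    spacing = config.genome_length // (config.n_genes + 1)
    if gene_len > spacing:
        raise ValueError("genes do not fit the genome; enlarge genome_length")
    for g in range(config.n_genes):
        g_start = spacing * (g + 1) - gene_len // 2
        exons = []
        pos = g_start
        for _ in range(config.exons_per_gene):
            exons.append(GenomeRegion(chrom, pos, pos + config.exon_length))
            pos += config.exon_length + config.intron_length
        g_end = exons[-1].end
        genes.append(Gene(f"gene{g + 1}", GenomeRegion(chrom, g_start, g_end), exons))
    model = GeneModel(genes)

    intron_spans = [
        (i.start, i.end) for g in genes for i in g.introns()
    ]
    gene_spans = [(g.region.start, g.region.end) for g in genes]

    def _is_intergenic(start: int, end: int, margin: int = 100) -> bool:
        return all(end + margin <= s or start - margin >= e for s, e in gene_spans)

    occupied: list[tuple[int, int]] = []

    # separation exceeds twice the discovery flank so distinct planted
    # precursors cannot share a candidate window
    def _free(start: int, end: int, min_sep: int = 200) -> bool:
        return all(end + min_sep <= s or start - min_sep >= e for s, e in occupied)

    def _place(length: int, placement: str, max_retries: int = 1000) -> int:
        for _ in range(max_retries):
            if placement == "intronic":
                lo, hi = intron_spans[rng.integers(len(intron_spans))]
                if hi - lo <= length:
                    continue
                start = int(rng.integers(lo, hi - length))
                if not (start >= lo and start + length <= hi):
                    continue
            else:
                start = int(rng.integers(0, config.genome_length - length))
                if not _is_intergenic(start, start + length):
                    continue
            if _free(start, start + length):
                occupied.append((start, start + length))
                return start
        raise RuntimeError(f"could not place a {placement} element after {max_retries} tries")

    hairpins: list[PlantedHairpin] = []
    adapter_head = config.adapter[0]

    def _plant(idx: int, loop_decoy: bool) -> PlantedHairpin:
        stem = config.decoy_stem_length if loop_decoy else config.stem_length
        loop = config.decoy_loop_length if loop_decoy else config.loop_length
        hp_len = 2 * stem + loop
        placement = "intronic" if idx % 2 else "intergenic"
        while True:
            seq = _build_hairpin(rng, stem, loop, config.bulge_rate)
            species = _draw_species(rng, config, seq, stem, loop, loop_decoy)
            # reject layouts whose species end with the adapter's first base:
            # trimming could not then distinguish insert from adapter remnant
            # and the ground-truth counts would be ill-defined
            if any(s[1][-1] == adapter_head for s in species):
                continue
            break
        start = _place(hp_len, placement)
        genome_arr[start : start + hp_len] = list(seq)
        kind = "decoy" if loop_decoy else "hp"
        return PlantedHairpin(
            hairpin_id=f"{kind}{idx + 1}",
            locus=GenomeRegion(chrom, start, start + hp_len),
            placement=placement,
            five_arm=(start, start + stem),
            three_arm=(start + stem + loop, start + hp_len),
            mature_arm=species[0][0].split(":")[0],
            is_loop_decoy=loop_decoy,
            species=[(role, s, c) for role, s, c in species],
        )

    for i in range(config.n_hairpins):
        hairpins.append(_plant(i, loop_decoy=False))
    for i in range(config.n_loop_decoys):
        hairpins.append(_plant(config.n_hairpins + i, loop_decoy=True))

    genome = {chrom: "".join(genome_arr)}

    # --- reference sets
    known_ids = [f"hsa-mir-sim-{i + 1}" for i in range(config.n_known_mirnas)]
    known_records = [
        (kid, _random_seq(rng, config.mature_length)) for kid in known_ids
    ]
    ncrna_records = [
        (f"ncRNA{i + 1}", _random_seq(rng, int(rng.integers(70, 120))))
        for i in range(config.n_decoys_per_category)
    ]
    rrna_records = [
        (f"rRNA{i + 1}", _random_seq(rng, int(rng.integers(100, 200))))
        for i in range(config.n_decoys_per_category)
    ]
    exon_records = []
    for g in genes:
        for j, e in enumerate(sorted(g.exons, key=lambda e: e.start), start=1):
            exon_records.append(
                (f"{g.gene_id}.exon{j}", genome[chrom][e.start : e.end])
            )
    refs = {
        "mature_miRNA": ReferenceSet("known_mirnas", "mature_miRNA", known_records),
        "ncRNA": ReferenceSet("ncrnas", "ncRNA", ncrna_records),
        "rRNA_mRNA": ReferenceSet("rrna_mrna", "rRNA_mRNA", rrna_records),
        "exon": ReferenceSet("exons", "exon", exon_records),
    }

    truth = SimTruth(
        hairpins=hairpins,
        known_counts={},
        decoy_counts={},
        species_counts={},
    )
    return genome, model, refs, truth


def _draw_species(
    rng: np.random.Generator,
    config: SimConfig,
    hairpin_seq: str,
    stem: int,
    loop: int,
    loop_decoy: bool,
) -> list[tuple[str, str, int]]:
    """Species (role, sequence, count) expressed from one hairpin.

    Roles are "<arm>:<kind>" with kind mature/isomir/star, or "loop:decoy"
    for large-loop decoys whose read sits in the terminal loop.
    """
    m = config.mature_length
    if loop_decoy:
        # read centered in the loop
        start = stem + (loop - m) // 2
        seq = hairpin_seq[start : start + m]
        count = _log_uniform_count(rng, *config.mature_abundance)
        return [("loop:decoy", seq, count)]
    arm = "five_prime" if rng.random() < 0.5 else "three_prime"
    arm_start = 0 if arm == "five_prime" else stem + loop
    slack = stem - m
    off = int(rng.integers(0, slack + 1))
    mature_start = arm_start + off
    mature = hairpin_seq[mature_start : mature_start + m]
    mature_count = _log_uniform_count(rng, *config.mature_abundance)
    species = [(f"{arm}:mature", mature, mature_count)]
    n_iso = int(rng.integers(0, config.max_isomirs + 1))
    used = {off}
    for _ in range(n_iso):
        shift = int(rng.integers(-3, 4))
        iso_off = off + shift
        if iso_off < 0 or iso_off > slack or iso_off in used:
            continue
        used.add(iso_off)
        iso = hairpin_seq[arm_start + iso_off : arm_start + iso_off + m]
        iso_count = _log_uniform_count(rng, 1.0, max(2.0, 0.3 * mature_count))
        species.append((f"{arm}:isomir", iso, iso_count))
    if rng.random() < config.star_probability:
        other = "three_prime" if arm == "five_prime" else "five_prime"
        other_start = (stem + loop) if other == "three_prime" else 0
        # star roughly opposite the mature: mirrored offset on the other arm
        star_off = max(0, min(slack, slack - off))
        star = hairpin_seq[other_start + star_off : other_start + star_off + m]
        star_count = _log_uniform_count(rng, *config.star_abundance)
        species.append((f"{other}:star", star, star_count))
    return species


def simulate_reads(
    genome: dict[str, str],
    refs: dict[str, ReferenceSet],
    truth: SimTruth,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> list[TagFileRecord]:
    """Adapter-bearing delivered reads, aggregated into tag-file records.

    Each species becomes reads of 33 or 35 nt: the species sequence followed
    by as much adapter as fits ((species + adapter) truncated to the
    delivered length). Species counts are recorded in truth.species_counts
    keyed by the trimmed (insert) sequence.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    read_counts: dict[str, int] = {}
    truth.species_counts = {}
    adapter_head = config.adapter[0]

    def _emit(species_seq: str, count: int):
        # the adapter remnant must stay detectable (>= 5 nt): long species go
        # into the longer delivered length
        eligible = [t for t in config.read_lengths if t - len(species_seq) >= 5]
        if eligible:
            target = int(rng.choice(eligible))
        else:
            target = max(config.read_lengths)
        read = (species_seq + config.adapter)[:target]
        read_counts[read] = read_counts.get(read, 0) + count
        truth.species_counts[species_seq] = (
            truth.species_counts.get(species_seq, 0) + count
        )

    for hp in truth.hairpins:
        for _, seq, count in hp.species:
            _emit(seq, count)

    # known-miRNA reads: exact copies of reference matures
    for kid, seq in refs["mature_miRNA"].records:
        if seq[-1] == adapter_head:
            continue  # skip trimming-ambiguous species (truth stays exact)
        count = _log_uniform_count(rng, 1.0, 3000.0)
        truth.known_counts[kid] = count
        _emit(seq, count)

    # decoy reads drawn from ncRNA / rRNA-mRNA / exon references
    lo, hi = config.species_length_range
    for category in ("ncRNA", "rRNA_mRNA", "exon"):
        total = 0
        for _, ref_seq in refs[category].records:
            length = int(rng.integers(lo, hi + 1))
            if len(ref_seq) <= length:
                continue
            for _ in range(20):
                start = int(rng.integers(0, len(ref_seq) - length))
                piece = ref_seq[start : start + length]
                if piece[-1] != adapter_head:
                    break
            else:
                continue
            count = _log_uniform_count(rng, 1.0, 500.0)
            total += count
            _emit(piece, count)
        truth.decoy_counts[category] = total

    return [TagFileRecord(seq, c) for seq, c in sorted(read_counts.items())]


def simulate_dataset(
    config: SimConfig | None = None, seed: int | None = None
):
    """Convenience wrapper: genome, gene model, refs, truth, and reads."""
    config = config or SimConfig()
    if seed is not None:
        config.seed = seed
    rng = np.random.default_rng(config.seed)
    genome, model, refs, truth = make_toy_genome(config, rng)
    reads = simulate_reads(genome, refs, truth, config, rng)
    return genome, model, refs, truth, reads


def simulate_null_counts(
    n_features: int,
    group_sizes: tuple[int, int] = (3, 3),
    dispersion: float = 0.05,
    seed: int = 0,
    planted: Sequence[tuple[int, float, str]] = (),
    mean_range: tuple[float, float] = (10.0, 1000.0),
    planted_mean_range: tuple[float, float] = (100.0, 1000.0),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Negative-binomial count matrix with optional planted fold changes.

    planted lists (feature index, fold, direction) applied to the second
    group; dispersion is the NB overdispersion (variance = mu + d * mu^2).
    Returns (matrix with columns A1..Ana, B1..Bnb; truth table).
    """
    rng = np.random.default_rng(seed)
    n_a, n_b = group_sizes
    means = np.exp(rng.uniform(np.log(mean_range[0]), np.log(mean_range[1]), n_features))
    fold = np.ones(n_features)
    direction = np.array(["null"] * n_features, dtype=object)
    for idx, f, d in planted:
        means[idx] = np.exp(
            rng.uniform(np.log(planted_mean_range[0]), np.log(planted_mean_range[1]))
        )
        fold[idx] = f if d == "up" else 1.0 / f
        direction[idx] = d

    def _nb(mu: np.ndarray, size: int) -> np.ndarray:
        r = 1.0 / dispersion
        p = r / (r + mu)
        return rng.negative_binomial(r, p[:, None], size=(n_features, size))

    a = _nb(means, n_a)
    b = _nb(means * fold, n_b)
    cols = [f"A{i + 1}" for i in range(n_a)] + [f"B{i + 1}" for i in range(n_b)]
    matrix = pd.DataFrame(
        np.hstack([a, b]),
        columns=cols,
        index=[f"feat{i + 1}" for i in range(n_features)],
    )
    truth = pd.DataFrame(
        {"mean": means, "fold": fold, "direction": direction}, index=matrix.index
    )
    return matrix, truth
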