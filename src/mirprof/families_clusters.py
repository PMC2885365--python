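"""Family grouping, naming, and genomic clustering of miRNAs.

Small RNAs sharing one precursor window form a family: the most abundant
member is the mature miRNA, same-arm variants are isomiRs, opposite-arm
members are stars. Naming: when the
predominant product is clear the pair is "<prefix>-N" / "<prefix>-N*",
otherwise "<prefix>-N-5p" / "<prefix>-N-3p". Loci (known and novel) within
20 kb chain into genomic clusters by single linkage.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .discovery import PrecursorCandidate
from .formats_io import GenomeRegion

DEFAULT_MAX_GAP = 20_000
DEFAULT_DOMINANCE_RATIO = 5.0
DEFAULT_NAME_PREFIX = "jnuhsa"

_ARM_RANK = {"five_prime": 0, "three_prime": 1}


@dataclass
class FamilyMember:
    tag_id: int
    sequence: str
    arm: str
    frequency: int
    sample: str = ""


@dataclass
class MiRNAFamily:
    precursor_id: str
    locus: GenomeRegion
    members: list[FamilyMember] = field(default_factory=list)
    representative: FamilyMember | None = None
    isomirs: list[FamilyMember] = field(default_factory=list)
    stars: list[FamilyMember] = field(default_factory=list)
    name: str = ""
    star_name: str = ""


@dataclass
class GenomicCluster:
    chrom: str
    members: list[tuple[str, GenomeRegion, bool]]  # (id, locus, is_novel)
    span: tuple[int, int]

    @property
    def kind(self) -> str:
        novel = [m[2] for m in self.members]
        if all(novel):
            return "novel_only"
        if any(novel):
            return "mixed"
        return "known_only"


def _merge_windows(
    candidates: Sequence[PrecursorCandidate],
) -> list[tuple[GenomeRegion, list[PrecursorCandidate]]]:
    """Merge overlapping candidate windows on the same chromosome/strand."""
    by_key: dict[tuple[str, str], list[PrecursorCandidate]] = defaultdict(list)
    for c in candidates:
        by_key[(c.locus.chrom, c.locus.strand)].append(c)
    merged: list[tuple[GenomeRegion, list[PrecursorCandidate]]] = []
    for (chrom, strand), group in sorted(by_key.items()):
        group.sort(key=lambda c: (c.locus.start, c.locus.end))
        cur_start, cur_end = group[0].locus.start, group[0].locus.end
        cur_members = [group[0]]
        for c in group[1:]:
            if c.locus.start < cur_end:  # >= 1 nt overlap
                cur_end = max(cur_end, c.locus.end)
                cur_members.append(c)
            else:
                merged.append((GenomeRegion(chrom, cur_start, cur_end, strand), cur_members))
                cur_start, cur_end, cur_members = c.locus.start, c.locus.end, [c]
        merged.append((GenomeRegion(chrom, cur_start, cur_end, strand), cur_members))
    return merged


def group_by_precursor(
    candidates: Sequence[PrecursorCandidate],
) -> list[MiRNAFamily]:
    """Group accepted candidates into families by shared (merged) precursor.

    Candidates whose windows overlap by >= 1 nt on the same strand share one
    precursor. Identical (tag, sample) duplicates within a window collapse
    to one member. Every accepted sRNA lands in exactly one family.
    """
    accepted = [c for c in candidates if c.accepted]
    families: list[MiRNAFamily] = []
    for idx, (region, group) in enumerate(_merge_windows(accepted), start=1):
        seen: set[tuple[int, str]] = set()
        members = []
        for c in sorted(group, key=lambda c: (c.sample, c.tag_id)):
            key = (c.tag_id, c.sample)
            if key in seen:
                continue
            seen.add(key)
            mature_seq = c.sequence[c.srna_span[0] : c.srna_span[1]]
            members.append(
                FamilyMember(c.tag_id, mature_seq, c.arm, c.frequency, c.sample)
            )
        fam = MiRNAFamily(
            precursor_id=f"prec{idx}_{region.chrom}_{region.start}_{region.end}{region.strand}",
            locus=region,
            members=members,
        )
        designate_members(fam)
        families.append(fam)
    return families


def designate_members(family: MiRNAFamily) -> MiRNAFamily:
    """Pick the representative mature member, isomiRs, and stars.

    Representative = highest total frequency (ties broken lexicographically
    by sequence); same-arm others are isomiRs, opposite-arm members stars.
    """
    if not family.members:
        raise ValueError("family has no members")
    rep = min(family.members, key=lambda m: (-m.frequency, m.sequence))
    family.representative = rep
    family.isomirs = [
        m for m in family.members if m is not rep and m.arm == rep.arm
    ]
    family.stars = [m for m in family.members if m.arm != rep.arm]
    return family


def assign_names(
    families: Sequence[MiRNAFamily],
    prefix: str = DEFAULT_NAME_PREFIX,
    dominance_ratio: float = DEFAULT_DOMINANCE_RATIO,
) -> list[MiRNAFamily]:
    """Deterministic family naming, ordered by genomic locus.

    With a clear predominant arm (representative frequency more than
    dominance_ratio times the best opposite-arm frequency, or no opposite
    arm at all) the family is "<prefix>-N" with star "<prefix>-N*"; when
    abundances cannot settle predominance the two arms become
    "<prefix>-N-5p" and "<prefix>-N-3p".
    """
    ordered = sorted(
        families, key=lambda f: (f.locus.chrom, f.locus.start, f.locus.end, f.locus.strand)
    )
    for n, fam in enumerate(ordered, start=1):
        rep = fam.representative
        if rep is None:
            designate_members(fam)
            rep = fam.representative
        opp_max = max((m.frequency for m in fam.stars), default=0)
        if opp_max == 0 or rep.frequency > dominance_ratio * opp_max:
            fam.name = f"{prefix}-{n}"
            fam.star_name = f"{prefix}-{n}*" if fam.stars else ""
        else:
            five = f"{prefix}-{n}-5p"
            three = f"{prefix}-{n}-3p"
            if rep.arm == "five_prime":
                fam.name, fam.star_name = five, three
            else:
                fam.name, fam.star_name = three, five
    return ordered


def deduplicate_across_samples(
    per_sample_families: Sequence[Sequence[MiRNAFamily]],
    prefix: str = DEFAULT_NAME_PREFIX,
    dominance_ratio: float = DEFAULT_DOMINANCE_RATIO,
) -> list[MiRNAFamily]:
    """Pool families from several samples and remove redundancy.

    Families whose precursor loci overlap on the same strand merge into one
    entry keeping every per-sample member; the merged set is renamed once so
    each final family carries a single name.
    """
    pooled: list[MiRNAFamily] = [f for fams in per_sample_families for f in fams]
    by_key: dict[tuple[str, str], list[MiRNAFamily]] = defaultdict(list)
    for f in pooled:
        by_key[(f.locus.chrom, f.locus.strand)].append(f)
    merged: list[MiRNAFamily] = []
    idx = 0
    for (chrom, strand), group in sorted(by_key.items()):
        group.sort(key=lambda f: (f.locus.start, f.locus.end))
        cur = [group[0]]
        cur_start, cur_end = group[0].locus.start, group[0].locus.end
        for f in group[1:]:
            if f.locus.start < cur_end:
                cur_end = max(cur_end, f.locus.end)
                cur.append(f)
            else:
                idx += 1
                merged.append(_fuse(cur, chrom, cur_start, cur_end, strand, idx))
                cur, cur_start, cur_end = [f], f.locus.start, f.locus.end
        idx += 1
        merged.append(_fuse(cur, chrom, cur_start, cur_end, strand, idx))
    return assign_names(merged, prefix=prefix, dominance_ratio=dominance_ratio)


def _fuse(
    group: list[MiRNAFamily], chrom: str, start: int, end: int, strand: str, idx: int
) -> MiRNAFamily:
    region = GenomeRegion(chrom, start, end, strand)
    members = [m for f in group for m in f.members]
    fam = MiRNAFamily(
        precursor_id=f"prec{idx}_{chrom}_{start}_{end}{strand}",
        locus=region,
        members=members,
    )
    return designate_members(fam)


def seed_sequence(mature: str) -> str | None:
    """Seed region: nucleotides 2-8 of the mature sequence (1-based)."""
    if len(mature) < 8:
        return None
    return mature[1:8].upper().replace("T", "U")


def seed_kinship(
    novel_mature: str, known_matures: Mapping[str, str]
) -> list[str]:
    """Known miRNAs whose seed (nt 2-8) is identical to the novel mature's."""
    seed = seed_sequence(novel_mature)
    if seed is None:
        return []
    return sorted(
        kid for kid, kseq in known_matures.items() if seed_sequence(kseq) == seed
    )


def cluster_loci(
    loci: Sequence[tuple[str, GenomeRegion, bool]],
    max_gap: int = DEFAULT_MAX_GAP,
) -> list[GenomicCluster]:
    """Single-linkage chaining of miRNA loci within max_gap per chromosome.

    The gap is measured end-to-start between neighbours (inclusive bound),
    chained transitively, strand-agnostic. Input tuples are
    (mirna id, locus, novelty flag).
    """
    by_chrom: dict[str, list[tuple[str, GenomeRegion, bool]]] = defaultdict(list)
    for item in loci:
        by_chrom[item[1].chrom].append(item)
    clusters: list[GenomicCluster] = []
    for chrom in sorted(by_chrom):
        group = sorted(by_chrom[chrom], key=lambda x: (x[1].start, x[1].end, x[0]))
        current = [group[0]]
        max_end = group[0][1].end
        for item in group[1:]:
            if item[1].start - max_end <= max_gap:
                current.append(item)
                max_end = max(max_end, item[1].end)
            else:
                clusters.append(_make_cluster(chrom, current))
                current, max_end = [item], item[1].end
        clusters.append(_make_cluster(chrom, current))
    return clusters


def _make_cluster(
    chrom: str, members: list[tuple[str, GenomeRegion, bool]]
) -> GenomicCluster:
    return GenomicCluster(
        chrom=chrom,
        members=members,
        span=(min(m[1].start for m in members), max(m[1].end for m in members)),
    )
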