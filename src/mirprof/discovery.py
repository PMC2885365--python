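"""Novel miRNA candidate discovery.

Exact genomic placements of unannotated tags are extended by 70 nt on each
side (potential precursor windows), folded with a nested base-pair
maximization dynamic program (Watson-Crick + G·U, minimum loop 3), and kept
only when the sequenced small RNA sits on an arm of the dominant hairpin
stem — mature miRNAs arise from the stem, never the terminal loop. External
hairpin classifiers can be plugged in as voting adapters; with none
configured the structural filter alone decides.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .annotate import GenomicHit
from .formats_io import GenomeRegion, fetch_region

DEFAULT_FLANK = 70

_ALPHABET = "ACGUN"
# Watson-Crick plus wobble; N pairs with nothing
_PAIRABLE = {
    ("A", "U"), ("U", "A"),
    ("G", "C"), ("C", "G"),
    ("G", "U"), ("U", "G"),
}


@dataclass
class FoldParams:
    min_loop: int = 3
    min_stem_pairs: int = 14
    max_mature_loop_overlap: int = 0
    max_bulge: int = 6  # widest interior bulge a stem may absorb per side

    def __post_init__(self):
        if self.min_loop < 3:
            raise ValueError("min_loop must be >= 3")
        if self.max_mature_loop_overlap < 0:
            raise ValueError("max_mature_loop_overlap must be >= 0")
        if self.max_bulge < 0:
            raise ValueError("max_bulge must be >= 0")


@dataclass
class PrecursorCandidate:
    locus: GenomeRegion
    sequence: str
    srna_span: tuple[int, int]  # mature read inside `sequence`
    tag_id: int = -1
    frequency: int = 0
    sample: str = ""
    structure: str = ""
    arm: str = ""  # five_prime/three_prime/loop/spanning/unpaired
    stem_pairs: int = 0
    votes: dict[str, str] = field(default_factory=dict)
    accepted: bool = False


def _pair_matrix(seq: str, min_loop: int) -> np.ndarray:
    rna = seq.upper().replace("T", "U")
    codes = np.array([_ALPHABET.find(c) for c in rna])
    codes[codes < 0] = 4  # unknown characters behave like N: never pair
    ok = np.zeros((5, 5), dtype=bool)
    for x, y in _PAIRABLE:
        ok[_ALPHABET.index(x), _ALPHABET.index(y)] = True
    pairable = ok[codes[:, None], codes[None, :]]
    n = len(seq)
    ij = np.arange(n)
    pairable &= (ij[None, :] - ij[:, None]) > min_loop
    return pairable


def fold_hairpin(seq: str, params: FoldParams | None = None) -> str:
    """Dot-bracket structure maximizing nested base pairs.

    Deterministic traceback: pairing (i, j) is preferred over bifurcation,
    and bifurcations split at the smallest possible k.
    """
    params = params or FoldParams()
    n = len(seq)
    if n == 0:
        return ""
    pairable = _pair_matrix(seq, params.min_loop)
    M = np.zeros((n, n), dtype=np.int32)
    for d in range(params.min_loop + 1, n):
        i_arr = np.arange(0, n - d)
        j_arr = i_arr + d
        for i, j in zip(i_arr, j_arr):
            # bifurcation over k in [i, j): M[i,k] + M[k+1,j]
            best = int((M[i, i:j] + M[i + 1 : j + 1, j]).max())
            if pairable[i, j]:
                best = max(best, int(M[i + 1, j - 1]) + 1)
            M[i, j] = best
    structure = ["."] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or M[i, j] == 0:
            continue
        if pairable[i, j] and M[i, j] == M[i + 1, j - 1] + 1:
            structure[i], structure[j] = "(", ")"
            stack.append((i + 1, j - 1))
            continue
        for k in range(i, j):
            if M[i, j] == M[i, k] + M[k + 1, j]:
                stack.append((i, k))
                stack.append((k + 1, j))
                break
    return "".join(structure)


def pair_table(structure: str) -> list[int]:
    """partner index per position, -1 if unpaired."""
    table = [-1] * len(structure)
    stack: list[int] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket")
            j = stack.pop()
            table[i], table[j] = j, i
    if stack:
        raise ValueError("unbalanced dot-bracket")
    return table


@dataclass
class StemLoop:
    five_arm: tuple[int, int]  # half-open span of the 5' strand of the stem
    loop: tuple[int, int]  # half-open span of the terminal loop
    three_arm: tuple[int, int]
    pairs: list[tuple[int, int]]  # the stem's base pairs (5' pos, 3' pos)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def find_stem_loops(structure: str, max_bulge: int = 6) -> list[StemLoop]:
    """All terminal stem-loops of a structure.

    Each hairpin (innermost pair enclosing only unpaired bases) is extended
    outward through its enclosing pairs, tolerating interior bulges of up to
    max_bulge nt per side, until a bifurcation, a wider bulge, or the
    molecule end.
    """
    table = pair_table(structure)
    n = len(structure)
    stems: list[StemLoop] = []
    for i in range(n):
        j = table[i]
        if j <= i:
            continue
        # terminal loop pair: nothing paired strictly inside
        if any(table[x] != -1 for x in range(i + 1, j)):
            continue
        inner_i, inner_j = i, j
        pairs = [(i, j)]
        a, b = i - 1, j + 1
        lo, hi = i, j
        skip_a = skip_b = 0
        while a >= 0 and b < n and skip_a <= max_bulge and skip_b <= max_bulge:
            if table[a] == b:
                pairs.append((a, b))
                lo, hi = a, b
                a -= 1
                b += 1
                skip_a = skip_b = 0
            elif table[a] == -1:
                a -= 1
                skip_a += 1
            elif table[b] == -1:
                b += 1
                skip_b += 1
            else:
                break  # branch point: pairs belong to another helix
        stems.append(
            StemLoop(
                five_arm=(lo, inner_i + 1),
                loop=(inner_i + 1, inner_j),
                three_arm=(inner_j, hi + 1),
                pairs=pairs,
            )
        )
    return stems


def _overlap(span: tuple[int, int], other: tuple[int, int]) -> int:
    return max(0, min(span[1], other[1]) - max(span[0], other[0]))


def _span_stem_counts(
    span: tuple[int, int], stem: StemLoop
) -> tuple[int, int, int]:
    """(positions of span pairing on the 5' stem strand, on the 3' strand,
    positions inside the terminal loop)."""
    span_set = range(span[0], span[1])
    five_pos = {a for a, _ in stem.pairs}
    three_pos = {b for _, b in stem.pairs}
    n_five = sum(1 for x in span_set if x in five_pos)
    n_three = sum(1 for x in span_set if x in three_pos)
    n_loop = _overlap(span, stem.loop)
    return n_five, n_three, n_loop


def locate_arm(
    candidate: PrecursorCandidate, params: FoldParams | None = None
) -> tuple[str, int]:
    """Where the sequenced sRNA sits in the dominant hairpin.

    The dominant stem-loop is the one whose stem pairing involves the sRNA
    the most (ties broken by total stem pairs); if no stem-loop involves the
    sRNA at all the candidate is unpaired — the folding window can report a
    structure not involving the read. An arm call requires the majority of
    the read to actually pair within the stem. Returns
    (arm label, stem pair count).
    """
    params = params or FoldParams()
    span = candidate.srna_span
    length = span[1] - span[0]
    stems = [
        s
        for s in find_stem_loops(candidate.structure, max_bulge=params.max_bulge)
        if _overlap(span, (s.five_arm[0], s.three_arm[1])) > 0
    ]
    if not stems:
        return "unpaired", 0
    stem = max(
        stems, key=lambda s: (sum(_span_stem_counts(span, s)[:2]), s.n_pairs)
    )
    n_five, n_three, n_loop = _span_stem_counts(span, stem)
    if n_loop > params.max_mature_loop_overlap:
        if n_five + n_three > n_loop and n_loop < length / 2:
            return "spanning", stem.n_pairs
        return "loop", stem.n_pairs
    if n_five + n_three < length / 2:
        return "unpaired", stem.n_pairs
    if n_five >= n_three:
        return "five_prime", stem.n_pairs
    return "three_prime", stem.n_pairs


def extract_candidates(
    hits: Sequence[GenomicHit],
    genome: Mapping[str, str],
    flank: int = DEFAULT_FLANK,
    frequencies: Mapping[int, int] | None = None,
    sample: str = "",
) -> list[PrecursorCandidate]:
    """Flanked precursor windows around exact genomic hits.

    The window is [start - flank, end + flank) clamped to the chromosome;
    minus-strand hits are extracted reverse-complemented with the sRNA span
    measured on the extracted strand.
    """
    out = []
    for hit in hits:
        chrom_len = len(genome[hit.chrom])
        w_start = max(0, hit.start - flank)
        w_end = min(chrom_len, hit.end + flank)
        region = GenomeRegion(hit.chrom, w_start, w_end, hit.strand)
        seq = fetch_region(genome, region)
        if hit.strand == "+":
            span = (hit.start - w_start, hit.end - w_start)
        else:
            span = (w_end - hit.end, w_end - hit.start)
        out.append(
            PrecursorCandidate(
                locus=region,
                sequence=seq,
                srna_span=span,
                tag_id=hit.tag_id,
                frequency=0 if frequencies is None else frequencies.get(hit.tag_id, 0),
                sample=sample,
            )
        )
    return out


ExternalClassifier = Callable[[PrecursorCandidate], str]  # returns accept/reject


def classify_candidate(
    candidate: PrecursorCandidate,
    params: FoldParams | None = None,
    externals: Mapping[str, ExternalClassifier] | None = None,
    consensus_k: int = 2,
) -> PrecursorCandidate:
    """Fold, locate the sRNA, and apply the structural filter plus any
    external classifier votes.

    Accept iff the sRNA is on a stem arm with at least min_stem_pairs pairs
    AND (no externals configured OR >= consensus_k of them accept). Failed
    adapters record a 'missing' vote excluded from the consensus count.
    """
    params = params or FoldParams()
    if not candidate.structure:
        candidate.structure = fold_hairpin(candidate.sequence, params)
    candidate.arm, candidate.stem_pairs = locate_arm(candidate, params)
    internal_ok = (
        candidate.arm in ("five_prime", "three_prime")
        and candidate.stem_pairs >= params.min_stem_pairs
    )
    candidate.votes["internal"] = "accept" if internal_ok else "reject"
    accepts = 0
    configured = 0
    for name, clf in (externals or {}).items():
        try:
            vote = clf(candidate)
        except Exception:
            candidate.votes[name] = "missing"
            continue
        candidate.votes[name] = vote
        configured += 1
        if vote == "accept":
            accepts += 1
    if externals and configured > 0:
        candidate.accepted = internal_ok and accepts >= consensus_k
    else:
        candidate.accepted = internal_ok
    return candidate


def discover_candidates(
    hits: Sequence[GenomicHit],
    genome: Mapping[str, str],
    flank: int = DEFAULT_FLANK,
    params: FoldParams | None = None,
    frequencies: Mapping[int, int] | None = None,
    sample: str = "",
    externals: Mapping[str, ExternalClassifier] | None = None,
    consensus_k: int = 2,
) -> list[PrecursorCandidate]:
    """End-to-end discovery stage: extract, fold, filter; returns all
    candidates with their accept/reject state and votes."""
    candidates = extract_candidates(
        hits, genome, flank=flank, frequencies=frequencies, sample=sample
    )
    # identical windows fold identically: cache structures
    cache: dict[str, str] = {}
    for cand in candidates:
        if cand.sequence in cache:
            cand.structure = cache[cand.sequence]
        else:
            cand.structure = fold_hairpin(cand.sequence, params or FoldParams())
            cache[cand.sequence] = cand.structure
        classify_candidate(cand, params, externals, consensus_k)
    return candidates
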