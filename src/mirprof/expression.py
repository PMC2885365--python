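"""Expression profiling and differential expression of known miRNAs.

Counts are normalized to transcripts per million (TPM): a tag's frequency
divided by the library's total clone count (the summed frequency of ALL
unique trimmed sequences, not only miRNA-derived ones) times 1e6.

Differential calls intersect two routes: a moderated difference statistic
in the style of significance analysis of microarrays (SAM) — a two-class
unpaired t-like score with a fudge factor s0 and a permutation-based FDR —
and a plain fold-change rule (> 2.5-fold versus every normal sample, with
features below 10 TPM everywhere ignored).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotate import AnnotationRecord
from .preprocess import SmallRNATag

DEFAULT_FC_THRESHOLD = 2.5
DEFAULT_TPM_FLOOR = 10.0
DEFAULT_TPM_PSEUDO = 0.5
DEFAULT_Q_THRESHOLD = 0.05


@dataclass(frozen=True)
class ExpressionEntry:
    mirna_id: str
    sample: str
    count: int
    tpm: float


@dataclass(frozen=True)
class SamResult:
    mirna_id: str
    d_score: float
    s: float
    s0: float
    q_value: float


@dataclass
class DeCall:
    mirna_id: str
    fc_vs_each_normal: dict[str, float]
    direction: str  # up or down
    passed_sam: bool = False
    passed_fc: bool = False

    @property
    def final(self) -> bool:
        return self.passed_sam and self.passed_fc


def tpm_normalize(
    counts: Mapping[str, int], total_clone_count: int, sample: str = ""
) -> list[ExpressionEntry]:
    """TPM per feature: count / total_clone_count * 1e6."""
    if total_clone_count <= 0:
        raise ValueError("total clone count must be positive")
    return [
        ExpressionEntry(fid, sample, c, c / total_clone_count * 1e6)
        for fid, c in counts.items()
    ]


def known_mirna_profile(
    annotations: Sequence[AnnotationRecord],
    tags: Sequence[SmallRNATag],
    total_clone_count: int | None = None,
) -> pd.DataFrame:
    """Per-miRNA summed counts and TPM for one sample.

    Each tag whose best hit is a mature miRNA contributes its full frequency
    to that miRNA. The total clone count defaults to the summed frequency of
    the whole tag library (all categories).
    """
    freq_by_id = {t.id: t.frequency for t in tags}
    sample = tags[0].sample if tags else ""
    if total_clone_count is None:
        total_clone_count = sum(freq_by_id.values())
    counts: dict[str, int] = {}
    for rec in annotations:
        if rec.category == "mature_miRNA" and rec.best_hit is not None:
            mid = rec.best_hit.reference_id
            counts[mid] = counts.get(mid, 0) + freq_by_id[rec.tag_id]
    entries = tpm_normalize(counts, total_clone_count, sample=sample)
    return pd.DataFrame(
        [(e.mirna_id, e.sample, e.count, e.tpm) for e in entries],
        columns=["mirna_id", "sample", "count", "tpm"],
    ).sort_values("count", ascending=False, ignore_index=True)


def detection_report(
    profiles: Sequence[pd.DataFrame], known_ids: Sequence[str]
) -> dict[str, int]:
    """How many known miRNAs were seen in >= 1 sample vs not detected at all."""
    seen: set[str] = set()
    for prof in profiles:
        seen.update(prof["mirna_id"])
    known = set(known_ids)
    return {
        "detected": len(seen & known),
        "not_detected": len(known - seen),
    }


# ---------------------------------------------------------------------------
# SAM statistic


def _pooled_s(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Gene-wise pooled standard-error term of the two-class unpaired score."""
    na, nb = a.shape[-1], b.shape[-1]
    if na + nb < 3:
        raise ValueError("need at least 3 samples overall")
    ssa = ((a - a.mean(axis=-1, keepdims=True)) ** 2).sum(axis=-1)
    ssb = ((b - b.mean(axis=-1, keepdims=True)) ** 2).sum(axis=-1)
    return np.sqrt((1.0 / na + 1.0 / nb) / (na + nb - 2) * (ssa + ssb))


def sam_d_statistic(
    group_a: Sequence[float], group_b: Sequence[float], s0: float
) -> float:
    """d = (mean_B - mean_A) / (s + s0) for one feature."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    s = float(_pooled_s(a, b))
    denom = s + s0
    if denom == 0:
        warnings.warn("both groups constant and s0 = 0: d undefined")
        return math.nan
    return float((b.mean() - a.mean()) / denom)


def _d_vector(a: np.ndarray, b: np.ndarray, s0: float) -> np.ndarray:
    s = _pooled_s(a, b)
    with np.errstate(divide="ignore", invalid="ignore"):
        return (b.mean(axis=-1) - a.mean(axis=-1)) / (s + s0)


def estimate_s0(a: np.ndarray, b: np.ndarray) -> float:
    """Fudge factor minimizing the coefficient of variation of |d| spread
    across percentile windows of s (the standard search); falls back to
    median(s) for tiny feature sets.
    """
    s = _pooled_s(a, b)
    n = len(s)
    if n < 50:
        return float(np.median(s))
    diff = b.mean(axis=-1) - a.mean(axis=-1)
    s_pcts = np.percentile(s, np.arange(0, 101, 5))
    window_edges = np.percentile(s, np.arange(0, 101, 1))
    best_s0, best_cv = float(np.median(s)), np.inf
    for alpha_idx, s0 in enumerate(s_pcts):
        d = diff / (s + s0)
        mads = []
        for lo, hi in zip(window_edges[:-1], window_edges[1:]):
            mask = (s >= lo) & (s <= hi)
            if mask.sum() < 2:
                continue
            di = d[mask]
            mads.append(np.median(np.abs(di - np.median(di))) / 0.64)
        mads = np.asarray(mads)
        if len(mads) < 2 or mads.mean() == 0:
            continue
        cv = mads.std() / mads.mean()
        if cv < best_cv:
            best_cv, best_s0 = cv, float(s0)
    return best_s0


def _enumerate_relabelings(n_a: int, n_b: int, max_exhaustive: int = 1000,
                           n_sampled: int = 500, seed: int = 0):
    """Column-index relabelings of an A/B design (group-A index tuples)."""
    total = math.comb(n_a + n_b, n_a)
    idx = list(range(n_a + n_b))
    if total <= max_exhaustive:
        return [np.array(c) for c in itertools.combinations(idx, n_a)]
    rng = np.random.default_rng(seed)
    return [np.sort(rng.choice(idx, size=n_a, replace=False)) for _ in range(n_sampled)]


def sam_fdr(
    d_obs: np.ndarray, d_perm: np.ndarray
) -> np.ndarray:
    """Per-feature q-values from permutation exceedance counts.

    q_i = median over permutations of #{perm scores with |d| >= |d_i|},
    divided by the observed count #{j : |d_j| >= |d_i|}, capped at 1 and
    monotonized to be non-increasing in |d|.
    """
    abs_obs = np.abs(d_obs)
    order = np.argsort(-abs_obs, kind="stable")
    n = len(abs_obs)
    q = np.full(n, np.nan)
    # exceedance counts per permutation for every observed cut, via one
    # searchsorted per permutation row
    perm_sorted = np.sort(np.abs(d_perm), axis=1)
    cuts = abs_obs[order]
    n_per_perm = perm_sorted.shape[1]
    counts = np.empty((perm_sorted.shape[0], len(cuts)))
    for p in range(perm_sorted.shape[0]):
        counts[p] = n_per_perm - np.searchsorted(perm_sorted[p], cuts, side="left")
    med = np.median(counts, axis=0)
    for rank, i in enumerate(order):
        observed = rank + 1  # features with |d| >= the cut at this feature
        q[i] = min(1.0, med[rank] / observed)
    # monotonize: q non-increasing in |d| means along decreasing |d| q is
    # non-decreasing; enforce a running maximum in that order
    running = 0.0
    for i in order:
        running = max(running, q[i])
        q[i] = running
    return q


def sam_analysis(
    matrix: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    s0: float | None = None,
    seed: int = 0,
    log_transform: bool = True,
    log_pseudo: float = DEFAULT_TPM_PSEUDO,
) -> pd.DataFrame:
    """SAM scores and q-values for a features x samples matrix.

    group_a are the reference samples (e.g. normals), group_b the condition;
    positive d means higher in group_b. Expression spanning several orders
    of magnitude makes the raw-scale statistic heavy-tailed (its spread
    grows with abundance), so the matrix is log2-transformed by default, the
    standard input scale for moderated t-like scores.
    """
    if min(len(group_a), len(group_b)) < 3:
        warnings.warn(
            "fewer than 3 samples in a group: the permutation null is "
            "degenerate and q-values are unstable"
        )
    if log_transform:
        matrix = np.log2(matrix + log_pseudo)
    a = matrix[list(group_a)].to_numpy(dtype=float)
    b = matrix[list(group_b)].to_numpy(dtype=float)
    if s0 is None:
        s0 = estimate_s0(a, b)
    d_obs = _d_vector(a, b, s0)
    all_cols = matrix[list(group_a) + list(group_b)].to_numpy(dtype=float)
    n_a = len(group_a)
    relabelings = _enumerate_relabelings(n_a, len(group_b), seed=seed)
    d_perm = np.empty((len(relabelings), len(matrix)))
    col_idx = np.arange(all_cols.shape[1])
    for p, a_idx in enumerate(relabelings):
        b_idx = np.setdiff1d(col_idx, a_idx)
        d_perm[p] = _d_vector(all_cols[:, a_idx], all_cols[:, b_idx], s0)
    q = sam_fdr(d_obs, d_perm)
    s = _pooled_s(a, b)
    return pd.DataFrame(
        {
            "mirna_id": matrix.index,
            "d_score": d_obs,
            "s": s,
            "s0": s0,
            "q_value": q,
        }
    ).set_index("mirna_id")


# ---------------------------------------------------------------------------
# Fold change and intersection


def fold_change_calls(
    tpm_matrix: pd.DataFrame,
    normals: Sequence[str],
    tumor: str | Sequence[str],
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    tpm_floor: float = DEFAULT_TPM_FLOOR,
    pseudo: float = DEFAULT_TPM_PSEUDO,
) -> dict[str, DeCall]:
    """Fold-change rule: called only if > fc_threshold versus EVERY normal.

    Features below tpm_floor in all compared samples are ignored. Ratios use
    max(tpm, pseudo) to avoid division by zero. A multi-sample tumor group is
    summarized by its mean TPM.
    """
    tumor_cols = [tumor] if isinstance(tumor, str) else list(tumor)
    calls: dict[str, DeCall] = {}
    for fid, row in tpm_matrix.iterrows():
        normal_vals = {s: float(row[s]) for s in normals}
        tumor_val = float(np.mean([row[s] for s in tumor_cols]))
        compared = list(normal_vals.values()) + [float(row[s]) for s in tumor_cols]
        if all(v < tpm_floor for v in compared):
            continue
        t = max(tumor_val, pseudo)
        ratios_up = {s: t / max(v, pseudo) for s, v in normal_vals.items()}
        if all(r > fc_threshold for r in ratios_up.values()):
            calls[fid] = DeCall(fid, ratios_up, "up", passed_fc=True)
            continue
        ratios_down = {s: max(v, pseudo) / t for s, v in normal_vals.items()}
        if all(r > fc_threshold for r in ratios_down.values()):
            calls[fid] = DeCall(fid, ratios_down, "down", passed_fc=True)
    return calls


def intersect_de(
    sam_table: pd.DataFrame,
    fc_calls: Mapping[str, DeCall],
    q_threshold: float = DEFAULT_Q_THRESHOLD,
) -> tuple[list[DeCall], dict[str, int]]:
    """Final DE set = SAM-significant AND fold-change-called, directions agreeing.

    Returns the final calls plus a Venn summary (sam-only / fc-only / both /
    direction conflicts).
    """
    sam_sig = sam_table[sam_table["q_value"] <= q_threshold]
    sam_ids = set(sam_sig.index)
    fc_ids = set(fc_calls)
    final: list[DeCall] = []
    conflicts = 0
    for fid in sorted(sam_ids & fc_ids):
        call = fc_calls[fid]
        d = float(sam_table.loc[fid, "d_score"])
        sam_dir = "up" if d > 0 else "down"
        if sam_dir != call.direction:
            conflicts += 1
            continue
        call.passed_sam = True
        final.append(call)
    venn = {
        "sam_only": len(sam_ids - fc_ids),
        "fc_only": len(fc_ids - sam_ids),
        "both": len(final),
        "direction_conflicts": conflicts,
    }
    return final, venn


def differential_expression(
    tpm_matrix: pd.DataFrame,
    normals: Sequence[str],
    tumor: str | Sequence[str],
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    tpm_floor: float = DEFAULT_TPM_FLOOR,
    q_threshold: float = DEFAULT_Q_THRESHOLD,
    seed: int = 0,
) -> tuple[list[DeCall], dict[str, int], pd.DataFrame]:
    """Full DE route: SAM (on log2 TPM) intersected with the fold-change rule.

    Returns (final calls, Venn summary, SAM table).
    """
    tumor_cols = [tumor] if isinstance(tumor, str) else list(tumor)
    sam = sam_analysis(tpm_matrix, list(normals), tumor_cols, seed=seed)
    fc = fold_change_calls(
        tpm_matrix, normals, tumor, fc_threshold=fc_threshold, tpm_floor=tpm_floor
    )
    final, venn = intersect_de(sam, fc, q_threshold=q_threshold)
    return final, venn, sam
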