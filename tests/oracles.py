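"""Independent reference implementations used only to check the package.

Each oracle deliberately takes a different algorithmic route from the
implementation it validates.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def hamming_hits(tag: str, ref: str, max_mismatches: int = 2) -> set[tuple[int, int]]:
    """Sliding-window Hamming scan: {(offset, mismatches)} with N never matching."""
    n, m = len(tag), len(ref)
    if m < n:
        return set()
    t = np.array([_CODE[c] for c in tag])
    r = np.array([_CODE[c] for c in ref])
    windows = np.lib.stride_tricks.sliding_window_view(r, n)
    mm = (windows != t) | (windows == 4) | (t == 4)
    counts = mm.sum(axis=1)
    return {(int(o), int(c)) for o, c in enumerate(counts) if c <= max_mismatches}


_PAIRS = {"AU", "UA", "GC", "CG", "GU", "UG"}


def max_nested_pairs(seq: str, min_loop: int = 3) -> int:
    """Maximum base pairs over all nested structures, by recursion on the
    fate of the first position (distinct from the interval DP it checks)."""
    rna = seq.upper().replace("T", "U")

    @lru_cache(maxsize=None)
    def best(i: int, j: int) -> int:
        if j - i <= min_loop:
            return 0
        top = best(i + 1, j)
        for l in range(i + min_loop + 1, j + 1):
            if rna[i] + rna[l] in _PAIRS:
                top = max(top, 1 + best(i + 1, l - 1) + best(l + 1, j))
        return top

    result = best(0, len(rna) - 1) if rna else 0
    best.cache_clear()
    return result


def enumerate_structures(seq: str, min_loop: int = 3) -> list[frozenset]:
    """Every nested pairing of a (short) sequence, as sets of (i, j) pairs."""
    rna = seq.upper().replace("T", "U")

    def go(i: int, j: int) -> list[frozenset]:
        if j - i <= min_loop:
            return [frozenset()]
        out = [s for s in go(i + 1, j)]
        for l in range(i + min_loop + 1, j + 1):
            if rna[i] + rna[l] in _PAIRS:
                for inner in go(i + 1, l - 1):
                    for outer in go(l + 1, j):
                        out.append(inner | outer | {(i, l)})
        return out

    return go(0, len(rna) - 1) if rna else [frozenset()]


def cluster_components(loci, max_gap: int):
    """Connected components of the 'same chromosome and gap <= max_gap'
    graph, via networkx; loci are (id, region, is_novel) tuples."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(len(loci)))
    for i in range(len(loci)):
        for j in range(i + 1, len(loci)):
            ri, rj = loci[i][1], loci[j][1]
            if ri.chrom != rj.chrom:
                continue
            gap = max(rj.start - ri.end, ri.start - rj.end)
            if gap <= max_gap:
                g.add_edge(i, j)
    return [sorted(c) for c in nx.connected_components(g)]
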