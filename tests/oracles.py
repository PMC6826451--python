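"""Independent reference implementations used only as test oracles.

These stay deliberately naive (dense O(n*m) dynamic programming, exhaustive
graph sweeps, literal formula evaluation) and share no code with the
package paths they check.
"""

from __future__ import annotations

from itertools import product

import numpy as np
from Bio.Align import substitution_matrices

_EDNAFULL = substitution_matrices.load("NUC.4.4")
_IDX = {c: i for i, c in enumerate(_EDNAFULL.alphabet)}
_NEG = -1e30


def _sub(a: str, b: str) -> float:
    return float(_EDNAFULL[_IDX[a], _IDX[b]])


def gotoh_global_free_endgaps(a: str, b: str, gap_open: float = 10.0,
                              gap_extend: float = 0.5) -> float:
    """Affine-gap Needleman-Wunsch with free end gaps.

    A run of k gaps costs gap_open + (k - 1) * gap_extend; leading gaps are
    encoded by the zero-initialized gap states and trailing gaps by taking
    the maximum over the last row and column.
    """
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)  # gap in b (a consumed)
    Y = np.full((n + 1, m + 1), _NEG)  # gap in a
    M[0, 0] = 0.0
    X[1:, 0] = 0.0
    Y[0, 1:] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _sub(a[i - 1], b[j - 1])
            M[i, j] = s + max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            X[i, j] = max(M[i - 1, j] - gap_open, X[i - 1, j] - gap_extend,
                          Y[i - 1, j] - gap_open)
            Y[i, j] = max(M[i, j - 1] - gap_open, Y[i, j - 1] - gap_extend,
                          X[i, j - 1] - gap_open)
    best = max(M[:, m].max(), X[:, m].max(), Y[:, m].max(),
               M[n, :].max(), X[n, :].max(), Y[n, :].max())
    return float(best)


def smith_waterman_local(a: str, b: str, gap_open: float = 10.0,
                         gap_extend: float = 0.5) -> float:
    """Affine-gap Smith-Waterman best local score (never negative)."""
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)
    Y = np.full((n + 1, m + 1), _NEG)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _sub(a[i - 1], b[j - 1])
            M[i, j] = s + max(0.0, M[i - 1, j - 1], X[i - 1, j - 1],
                              Y[i - 1, j - 1])
            X[i, j] = max(M[i - 1, j] - gap_open, X[i - 1, j] - gap_extend,
                          Y[i - 1, j] - gap_open)
            Y[i, j] = max(M[i, j - 1] - gap_open, Y[i, j - 1] - gap_extend,
                          X[i, j - 1] - gap_open)
            best = max(best, M[i, j])
    return float(best)


def silhouette_textbook(points: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Literal textbook silhouette (cohesion divisor N_k - 1), Euclidean."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    labels = np.asarray(labels)
    n = pts.shape[0]
    out = np.zeros(n)
    for i in range(n):
        same = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not same:
            continue
        a = np.mean([np.linalg.norm(pts[i] - pts[j]) for j in same])
        b = min(
            np.mean([np.linalg.norm(pts[i] - pts[j])
                     for j in range(n) if labels[j] == h])
            for h in set(labels.tolist()) - {labels[i]})
        out[i] = (b - a) / max(a, b)
    return out


def best_partition_sse(points: np.ndarray, k: int) -> float:
    """Exhaustive k-means optimum: minimal within-cluster sum of squares
    over every assignment of n points to k clusters."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    n = pts.shape[0]
    best = np.inf
    for assign in product(range(k), repeat=n):
        if len(set(assign)) < k:
            continue
        sse = 0.0
        arr = np.asarray(assign)
        for c in range(k):
            members = pts[arr == c]
            sse += ((members - members.mean(axis=0)) ** 2).sum()
        best = min(best, sse)
    return float(best)


def exhaustive_lcc(edges: list[tuple[str, str]], nodes: list[str]) -> tuple[int, int]:
    """Largest connected component by BFS from every node; returns
    (component size, internal edge count) with the (size, edges) maximum."""
    adj: dict[str, set[str]] = {v: set() for v in nodes}
    for u, v in edges:
        if u in adj and v in adj:
            adj[u].add(v)
            adj[v].add(u)
    seen: set[str] = set()
    best = (0, 0)
    for start in nodes:
        if start in seen:
            continue
        comp = {start}
        queue = [start]
        while queue:
            u = queue.pop()
            for w in adj[u]:
                if w not in comp:
                    comp.add(w)
                    queue.append(w)
        seen |= comp
        n_edges = sum(1 for u in comp for w in adj[u] if w in comp) // 2
        best = max(best, (len(comp), n_edges))
    return best


def scan_sds_reference(window: str, motifs: tuple[str, ...],
                       search_len: int) -> tuple[str, int] | None:
    """Brute-force Shine-Dalgarno reference: enumerate every motif
    occurrence whose first base lies within search_len of the window end,
    keep the longest motif, break ties by smallest offset."""
    hits = []
    lw = len(window)
    for motif in motifs:
        for start in range(lw - len(motif) + 1):
            if window[start : start + len(motif)] == motif:
                offset = lw - start
                if offset <= search_len:
                    hits.append((len(motif), -offset, motif, offset))
    if not hits:
        return None
    hits.sort(reverse=True)
    return hits[0][2], hits[0][3]
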