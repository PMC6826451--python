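"""Normalized-Laplacian spectral clustering with eigengap model selection.

Pipeline: L_sym = D^{-1/2} (D - W) D^{-1/2} of the weighted adjacency W;
the ascending spectrum's largest gap suggests the number of clusters k
(for an exact union of k components the null eigenvalue has multiplicity k
and the gap is sharp; mixed data perturbs those zeros upwards); the first
k eigenvectors, row-normalized to unit length, embed each sequence as a
point on the unit sphere in R^k; Lloyd's k-means partitions the embedding;
silhouettes grade the partition.

k selection is advisory: the spectrum and the full gap table are always
reported and the caller may override k, e.g. on the grounds of downstream
compositional structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.linalg import eigh
from scipy.spatial.distance import cdist


@dataclass
class LaplacianSpectrum:
    eigenvalues: np.ndarray  # ascending
    eigenvectors: np.ndarray  # columns, sign-canonicalized
    suggested_k: Optional[int] = None
    gap_table: Optional[np.ndarray] = None  # gap at each candidate k


@dataclass
class Embedding:
    U: np.ndarray  # N x k eigenvector block
    T: np.ndarray  # row-normalized
    degenerate_rows: list[int] = field(default_factory=list)


@dataclass
class ClusteringResult:
    ids: list[str]
    labels: np.ndarray  # cluster index per id, clusters named C0, C1, ...
    centroids: np.ndarray
    silhouettes: Optional[np.ndarray] = None
    cluster_silhouette_means: Optional[dict[int, float]] = None

    def members(self, cluster: int) -> list[str]:
        return [i for i, l in zip(self.ids, self.labels) if l == cluster]


def normalized_laplacian(W: np.ndarray) -> np.ndarray:
    """L_sym = D^{-1/2} (D - W) D^{-1/2} for symmetric non-negative W with
    zero diagonal and strictly positive degrees."""
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("W must be square")
    if not np.allclose(W, W.T):
        raise ValueError("W must be symmetric")
    if np.any(W < 0):
        raise ValueError("W must be non-negative")
    if np.any(np.diag(W) != 0):
        raise ValueError("W must have zero diagonal")
    d = W.sum(axis=1)
    if np.any(d <= 0):
        raise ValueError(
            "zero-degree node: drop isolated nodes before building L_sym")
    inv_sqrt = 1.0 / np.sqrt(d)
    L = -W * np.outer(inv_sqrt, inv_sqrt)
    np.fill_diagonal(L, 1.0)
    return L


def eigenspectrum(L: np.ndarray, sym_tol: float = 1e-8) -> LaplacianSpectrum:
    """Full ascending spectrum with orthonormal, sign-canonicalized
    eigenvectors (largest-magnitude entry made positive)."""
    L = np.asarray(L, dtype=float)
    if not np.allclose(L, L.T, atol=sym_tol):
        raise ValueError("matrix not symmetric within tolerance")
    vals, vecs = eigh((L + L.T) / 2.0)
    for j in range(vecs.shape[1]):
        k = np.argmax(np.abs(vecs[:, j]))
        if vecs[k, j] < 0:
            vecs[:, j] = -vecs[:, j]
    return LaplacianSpectrum(vals, vecs)


def suggest_k(eigenvalues: Sequence[float], k_max: int = 20) -> tuple[int, np.ndarray]:
    """Eigengap heuristic: k = argmax over 2 <= k <= k_max of
    lambda_{k+1} - lambda_k (1-based indexing).

    Returns (k, gap table aligned to candidates 2..k_max).  Ties break to
    the largest k with a warning; a flat spectrum therefore lands on k_max.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    k_max = min(k_max, lam.size - 1)
    if k_max < 2:
        raise ValueError("need at least 3 eigenvalues to suggest k")
    ks = np.arange(2, k_max + 1)
    gaps = lam[ks] - lam[ks - 1]  # lambda_{k+1} - lambda_k, 0-based
    best = gaps.max()
    tied = np.flatnonzero(gaps >= best - 1e-12)
    if tied.size > 1:
        warnings.warn(
            f"flat eigengap: {tied.size} candidate k values tie; "
            "taking the largest", stacklevel=2)
    k = int(ks[tied[-1]])
    return k, gaps


def spectral_embedding(eigenvectors: np.ndarray, k: int) -> Embedding:
    """First k eigenvectors as columns, rows scaled to unit norm.

    Rows of numerically zero norm are replaced by the canonical first
    basis vector and flagged.
    """
    vecs = np.asarray(eigenvectors, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > vecs.shape[0]:
        raise ValueError("k exceeds number of points")
    U = vecs[:, :k].copy()
    norms = np.linalg.norm(U, axis=1)
    degenerate = list(np.flatnonzero(norms < 1e-12))
    T = U.copy()
    for i in degenerate:
        T[i] = 0.0
        T[i, 0] = 1.0
        norms[i] = 1.0
    T = T / norms[:, None]
    return Embedding(U, T, degenerate)


def kmeans(points: np.ndarray, k: int, tol: float = 1e-8, n_init: int = 10,
           rng: Optional[np.random.Generator] = None,
           max_iter: int = 500) -> tuple[np.ndarray, np.ndarray]:
    """Lloyd's algorithm, Euclidean metric, best of ``n_init`` restarts.

    Initial centroids are sampled from the (distinct) points; iteration
    stops when the largest centroid displacement falls below ``tol``.  An
    emptied cluster is reseeded at the point farthest from its assigned
    centroid.  Returns (labels, centroids) of the restart with the lowest
    within-cluster sum of squares.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    n = pts.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds number of points {n}")
    distinct = np.unique(pts, axis=0)
    if k > distinct.shape[0]:
        raise ValueError(f"k={k} exceeds number of distinct points")
    rng = np.random.default_rng() if rng is None else rng
    best_sse = np.inf
    best: tuple[np.ndarray, np.ndarray] | None = None
    for _ in range(n_init):
        centroids = distinct[rng.choice(distinct.shape[0], size=k, replace=False)]
        for _ in range(max_iter):
            dists = cdist(pts, centroids)
            labels = dists.argmin(axis=1)
            new_centroids = centroids.copy()
            for c in range(k):
                members = pts[labels == c]
                if members.shape[0] == 0:
                    # reseed at the point farthest from its current centroid
                    far = dists[np.arange(n), labels].argmax()
                    new_centroids[c] = pts[far]
                    labels[far] = c
                else:
                    new_centroids[c] = members.mean(axis=0)
            shift = np.abs(new_centroids - centroids).max()
            centroids = new_centroids
            if shift < tol:
                break
        dists = cdist(pts, centroids)
        labels = dists.argmin(axis=1)
        sse = float((dists[np.arange(n), labels] ** 2).sum())
        if sse < best_sse:
            best_sse = sse
            best = (labels.copy(), centroids.copy())
    assert best is not None
    return best


def silhouette_values(
    points: np.ndarray, labels: np.ndarray, normalization: str = "cluster_size",
) -> tuple[np.ndarray, dict[int, float]]:
    """Per-point silhouettes s(i) = (b - a) / max(a, b), Euclidean metric.

    ``normalization`` controls the cohesion term a(i): ``cluster_size`` divides
    the intra-cluster distance sum (excluding i itself) by the full cluster
    size N_k; ``standard`` divides by N_k - 1 (the textbook mean over the
    other members).  The two agree in the large-cluster limit but not
    exactly; both are exposed rather than silently correcting either.
    Singleton clusters get s(i) = 0.
    """
    if normalization not in ("cluster_size", "standard"):
        raise ValueError(f"unknown normalization {normalization!r}")
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    if clusters.size < 2:
        raise ValueError("silhouette requires at least two clusters")
    D = cdist(pts, pts)
    n = pts.shape[0]
    s = np.zeros(n)
    for i in range(n):
        k = labels[i]
        same = labels == k
        nk = int(same.sum())
        if nk == 1:
            s[i] = 0.0
            continue
        intra_sum = D[i, same].sum()  # D[i, i] = 0 excludes i naturally
        a = intra_sum / (nk if normalization == "cluster_size" else nk - 1)
        b = min(D[i, labels == h].mean() for h in clusters if h != k)
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    means = {int(c): float(s[labels == c].mean()) for c in clusters}
    return s, means


def cluster_graph(
    ids: Sequence[str], W: np.ndarray, k: Optional[int] = None, k_max: int = 20,
    tol: float = 1e-8, n_init: int = 10,
    rng: Optional[np.random.Generator] = None,
    silhouette_normalization: str = "cluster_size",
) -> tuple[ClusteringResult, LaplacianSpectrum, Embedding]:
    """Full spectral-clustering pass over a connected weighted adjacency."""
    L = normalized_laplacian(W)
    spec = eigenspectrum(L)
    spec.suggested_k, spec.gap_table = suggest_k(
        spec.eigenvalues, min(k_max, len(ids) - 1))
    k_used = spec.suggested_k if k is None else int(k)
    emb = spectral_embedding(spec.eigenvectors, k_used)
    labels, centroids = kmeans(emb.T, k_used, tol=tol, n_init=n_init, rng=rng)
    if k_used >= 2:
        sil, sil_means = silhouette_values(emb.T, labels,
                                           silhouette_normalization)
    else:
        sil, sil_means = np.zeros(len(ids)), {0: 0.0}
    result = ClusteringResult(list(ids), labels, centroids, sil, sil_means)
    return result, spec, emb
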