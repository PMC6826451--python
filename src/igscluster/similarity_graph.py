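"""Similarity threshold estimation and adjacency construction.

Even two random sequences obtain a positive global-alignment score, so the
raw similarity matrix describes a fully connected, noisy graph.  The
threshold s* estimates that background score from randomized sequences;
scores at or above s* survive as weighted edges, everything else is cut.

Two estimators are provided:

* ``global_shuffle`` -- shuffle every sequence, rescore all pairs, take the
  mean; repeat R times and average the iteration means.
* ``self_shuffle`` -- score each original sequence against a number of
  shuffled realizations of itself and average over all sequences and
  realizations.  Because shuffling preserves composition, this estimator
  retains each sequence's compositional self-similarity and is typically
  the higher of the two, giving a sparser graph that is better suited to
  short sequences.  It is the pipeline default.

After thresholding, surviving scores are divided by the largest surviving
score, so edge weights lie in (0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np

from .pairwise_alignment import AlignmentParams, SimilarityMatrix, make_aligner


@dataclass(frozen=True)
class ThresholdEstimate:
    method: str  # 'global_shuffle' or 'self_shuffle'
    s_star: float
    n_iterations: int
    iteration_values: tuple[float, ...] = ()


@dataclass
class AdjacencyGraph:
    """Thresholded, max-normalized weighted adjacency of the IGS graph."""

    ids: list[str]
    weights: np.ndarray
    s_star: float

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if not np.allclose(w, w.T):
            raise ValueError("adjacency not symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("adjacency diagonal must be zero")
        self.weights = w

    @property
    def degrees(self) -> np.ndarray:
        return self.weights.sum(axis=1)

    @property
    def isolated(self) -> list[str]:
        """Ids with zero degree; they carry no similarity signal above the
        threshold and are excluded from spectral clustering."""
        return [self.ids[i] for i in np.flatnonzero(self.degrees == 0)]

    def connected_submatrix(self) -> tuple[list[str], np.ndarray]:
        keep = np.flatnonzero(self.degrees > 0)
        return [self.ids[i] for i in keep], self.weights[np.ix_(keep, keep)]


def shuffle_sequence(seq: str, rng: np.random.Generator) -> str:
    """Uniform random permutation of the characters; composition preserved."""
    if not seq:
        raise ValueError("empty sequence")
    chars = np.frombuffer(seq.encode(), dtype="S1")
    return rng.permutation(chars).tobytes().decode()


def estimate_threshold_global(
    sequences: Sequence[str],
    params: AlignmentParams = AlignmentParams(),
    n_iterations: int = 3,
    rng: Optional[np.random.Generator] = None,
    pair_subsample: Optional[int] = None,
) -> ThresholdEstimate:
    """Background score from whole-set shuffles.

    Each iteration shuffles every sequence and averages the scores of all
    pairs (or of ``pair_subsample`` random pairs -- each iteration is
    O(N^2) alignments at full enumeration).  s* is the mean of the
    iteration means.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    aligner = make_aligner(params)
    all_pairs = list(combinations(range(len(sequences)), 2))
    means = []
    for _ in range(n_iterations):
        shuffled = [shuffle_sequence(s, rng) for s in sequences]
        pairs = all_pairs
        if pair_subsample is not None and pair_subsample < len(all_pairs):
            idx = rng.choice(len(all_pairs), size=pair_subsample, replace=False)
            pairs = [all_pairs[i] for i in idx]
        scores = [aligner.score(shuffled[i], shuffled[j]) for i, j in pairs]
        means.append(float(np.mean(scores)))
    return ThresholdEstimate("global_shuffle", float(np.mean(means)),
                             n_iterations, tuple(means))


def estimate_threshold_self(
    sequences: Sequence[str],
    params: AlignmentParams = AlignmentParams(),
    n_shuffles: int = 10,
    rng: Optional[np.random.Generator] = None,
) -> ThresholdEstimate:
    """Background score from self-shuffles: each sequence against
    ``n_shuffles`` random reorderings of itself, averaged over everything."""
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    aligner = make_aligner(params)
    scores = []
    for seq in sequences:
        for _ in range(n_shuffles):
            scores.append(aligner.score(seq, shuffle_sequence(seq, rng)))
    return ThresholdEstimate("self_shuffle", float(np.mean(scores)), n_shuffles)


def build_adjacency(sim: SimilarityMatrix, s_star: float) -> AdjacencyGraph:
    """Threshold (keep scores >= s*) then divide by the maximum survivor.

    The comparison happens on the raw score scale; normalization comes
    after thresholding.
    """
    s = sim.scores.copy()
    np.fill_diagonal(s, 0.0)
    w = np.where(s >= s_star, s, 0.0)
    np.fill_diagonal(w, 0.0)
    wmax = w.max()
    if wmax <= 0:
        raise ValueError("threshold removes all edges")
    w = w / wmax
    return AdjacencyGraph(list(sim.ids), w, float(s_star))
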