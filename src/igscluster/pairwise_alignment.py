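"""All-vs-all pairwise alignment scoring of intergenic sequences.

Scores come from exact affine-gap dynamic programming (Biopython's
``PairwiseAligner``): Needleman-Wunsch in global mode with free end gaps,
Smith-Waterman in local mode.  The substitution table is the standard
EDNAFULL nucleotide matrix (match +5, mismatch -4 among A/C/G/T, IUPAC
ambiguity rows included).

Gap convention: a run of k consecutive gaps costs
``gap_open + (k - 1) * gap_extend``, and in global mode gaps at either end
of either sequence are free.  With the default penalties (open 10,
extend 0.5) the all-end-gap alignment of two sequences scores 0, so global
scores of equal-length sequences are bounded below by 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

EDNAFULL = substitution_matrices.load("NUC.4.4")
IUPAC_ALPHABET = frozenset(EDNAFULL.alphabet)  # ATGCSWRYKMBVHDN


@dataclass(frozen=True)
class AlignmentParams:
    mode: str = "global"  # or 'local'
    gap_open: float = 10.0
    gap_extend: float = 0.5
    end_gaps_free: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("global", "local"):
            raise ValueError(f"invalid mode {self.mode!r}")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be non-negative")


def make_aligner(params: AlignmentParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = EDNAFULL
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    if params.mode == "global":
        aligner.mode = "global"
        if params.end_gaps_free:
            aligner.end_insertion_score = 0.0
            aligner.end_deletion_score = 0.0
    else:
        aligner.mode = "local"
    return aligner


def _validate(seq: str) -> str:
    s = seq.upper()
    bad = set(s) - IUPAC_ALPHABET
    if bad:
        raise ValueError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    if not s:
        raise ValueError("empty sequence")
    return s


def align_pair(seq_a: str, seq_b: str,
               params: AlignmentParams = AlignmentParams(),
               aligner: Optional[Align.PairwiseAligner] = None) -> float:
    """Best alignment score for one pair; deterministic exact DP."""
    a, b = _validate(seq_a), _validate(seq_b)
    if aligner is None:
        aligner = make_aligner(params)
    return float(aligner.score(a, b))


@dataclass
class SimilarityMatrix:
    """Symmetric matrix of pairwise alignment scores; diagonal fixed at 0.

    Self-alignments are never computed: a self-score of 5L per node would
    dominate the degree normalization downstream without carrying any
    between-sequence information.
    """

    ids: list[str]
    scores: np.ndarray
    params: AlignmentParams = field(default_factory=AlignmentParams)

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        if s.shape != (len(self.ids), len(self.ids)):
            raise ValueError("score matrix shape does not match ids")
        if not np.allclose(s, s.T):
            raise ValueError("score matrix is not symmetric")
        self.scores = s

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.ids, columns=self.ids)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path,
                 params: AlignmentParams = AlignmentParams()) -> "SimilarityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(dtype=float), params)


def similarity_matrix(sequences: Sequence[str], ids: Optional[Sequence[str]] = None,
                      params: AlignmentParams = AlignmentParams()) -> SimilarityMatrix:
    """Score all N(N-1)/2 pairs once and mirror into a symmetric matrix."""
    n = len(sequences)
    if n < 2:
        raise ValueError("need at least two sequences")
    lengths = {len(s) for s in sequences}
    if len(lengths) > 1:
        raise ValueError(f"sequences must be equal length, got {sorted(lengths)}")
    if ids is None:
        ids = [f"igs{i:05d}" for i in range(n)]
    ids = list(ids)
    if len(set(ids)) != n:
        raise ValueError("duplicate sequence ids")
    seqs = [_validate(s) for s in sequences]
    aligner = make_aligner(params)
    scores = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            s = float(aligner.score(seqs[i], seqs[j]))
            scores[i, j] = scores[j, i] = s
    return SimilarityMatrix(ids, scores, params)
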