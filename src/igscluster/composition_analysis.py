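"""Base Composition Analysis (BCA) and homogeneous-segment statistics.

BCA turns a set of N equal-length sequences into per-position nucleotide
densities rho_x(l) for x in {A, T, G, C}, with positions indexed
l = -L ... -1 relative to the anchor (position 0 is the TSS -- the first
nucleotide of the Shine-Dalgarno motif -- or the TSC when none was found;
position 0 itself is not part of the IGS).  A centered moving average with
half-window a smooths the raw profile; windows truncate at the profile
ends and renormalize by the covered width, which keeps the cross-nucleotide
sum exactly 1 everywhere.

Segment statistics count the regular weak-nucleotide motifs that drive the
compositional clusters apart: maximal homopolymer runs of A, of T, and
maximal period-2 alternating AT runs, each reported when at least
``min_len`` (default 6) bases long.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .annotation_io import IGSRecord

NUCLEOTIDES = ("A", "T", "G", "C")
SEGMENT_TYPES = ("A", "T", "AT")


@dataclass
class BCAProfile:
    positions: np.ndarray  # l = -L .. -1
    densities: dict[str, np.ndarray]  # nucleotide -> rho_x(l)
    n_sequences: int
    half_window: int = 0  # smoothing half-window a (0 = raw)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"position": self.positions})
        for x in NUCLEOTIDES:
            df[f"rho_{x}"] = self.densities[x]
        return df


def _sequences(records: Sequence[Union[str, IGSRecord]]) -> list[str]:
    return [r.sequence if isinstance(r, IGSRecord) else r for r in records]


def bca(records: Sequence[Union[str, IGSRecord]]) -> BCAProfile:
    """Positional nucleotide densities over equal-length sequences.

    Ambiguity codes contribute to no nucleotide, so the per-position sum
    over A, T, G, C is 1 for clean sequences and at most 1 otherwise.
    """
    seqs = _sequences(records)
    if not seqs:
        raise ValueError("empty sequence set")
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        raise ValueError(f"sequences must be equal length, got {sorted(lengths)}")
    L = lengths.pop()
    mat = np.frombuffer("".join(s.upper() for s in seqs).encode(),
                        dtype="S1").reshape(len(seqs), L)
    densities = {x: (mat == x.encode()).mean(axis=0) for x in NUCLEOTIDES}
    return BCAProfile(np.arange(-L, 0), densities, len(seqs))


def smooth_bca(profile: BCAProfile, a: int = 15) -> BCAProfile:
    """Centered moving average over [l - a, l + a].

    At the profile boundaries the window truncates to the available
    positions and renormalizes by the true covered width instead of
    padding, avoiding edge artifacts.
    """
    if a < 0:
        raise ValueError("half-window a must be >= 0")
    if a == 0:
        return BCAProfile(profile.positions.copy(),
                          {x: v.copy() for x, v in profile.densities.items()},
                          profile.n_sequences, 0)
    kernel = np.ones(2 * a + 1)
    counts = np.convolve(np.ones_like(profile.positions, dtype=float),
                         kernel, mode="same")
    smoothed = {
        x: np.convolve(v, kernel, mode="same") / counts
        for x, v in profile.densities.items()
    }
    return BCAProfile(profile.positions.copy(), smoothed,
                      profile.n_sequences, a)


@dataclass
class SegmentCounts:
    counts: dict[str, int] = field(default_factory=lambda: dict.fromkeys(SEGMENT_TYPES, 0))
    histograms: dict[str, Counter] = field(
        default_factory=lambda: {t: Counter() for t in SEGMENT_TYPES})

    def add(self, seg_type: str, length: int) -> None:
        self.counts[seg_type] += 1
        self.histograms[seg_type][length] += 1

    def merge(self, other: "SegmentCounts") -> None:
        for t in SEGMENT_TYPES:
            self.counts[t] += other.counts[t]
            self.histograms[t].update(other.histograms[t])


def homogeneous_segments(sequence: str, min_len: int = 6) -> SegmentCounts:
    """Count maximal A-runs, T-runs and alternating-AT runs of length >=
    ``min_len``.

    Maximality is per run type: a homopolymer run is not extendable by the
    same letter; an alternating run has letters in {A, T} with no two equal
    neighbours and (by alternation at length >= 2) contains both letters.
    Homopolymer and alternating runs are counted independently.
    """
    s = sequence.upper()
    out = SegmentCounts()
    n = len(s)
    # homopolymer runs
    for base in ("A", "T"):
        i = 0
        while i < n:
            if s[i] != base:
                i += 1
                continue
            j = i
            while j < n and s[j] == base:
                j += 1
            if j - i >= min_len:
                out.add(base, j - i)
            i = j
    # alternating AT runs: maximal stretches over {A,T} with no equal neighbours
    i = 0
    while i < n:
        if s[i] not in "AT":
            i += 1
            continue
        j = i
        while j + 1 < n and s[j + 1] in "AT" and s[j + 1] != s[j]:
            j += 1
        if j - i + 1 >= min_len:
            out.add("AT", j - i + 1)
        i = j + 1
    return out


def cluster_segment_summary(
    records: Sequence[Union[str, IGSRecord]],
    labels: Sequence[int] | Mapping[str, int],
    min_len: int = 6,
) -> pd.DataFrame:
    """Per-cluster totals of homogeneous segments, one row per cluster with
    A/T/AT counts and the T:A and A:AT ratios."""
    seqs = _sequences(records)
    if isinstance(labels, Mapping):
        keyed = []
        for r in records:
            if not isinstance(r, IGSRecord) or r.tu_id not in labels:
                raise ValueError("unlabeled record")
            keyed.append(labels[r.tu_id])
        labels = keyed
    labels = list(labels)
    if len(labels) != len(seqs):
        raise ValueError("labels do not cover all records")
    per_cluster: dict[int, SegmentCounts] = {}
    for seq, lab in zip(seqs, labels):
        per_cluster.setdefault(int(lab), SegmentCounts()).merge(
            homogeneous_segments(seq, min_len))
    rows = []
    for lab in sorted(per_cluster):
        c = per_cluster[lab].counts
        rows.append({
            "cluster": f"C{lab}",
            "A_segments": c["A"],
            "T_segments": c["T"],
            "AT_segments": c["AT"],
            "T_over_A": c["T"] / c["A"] if c["A"] else np.inf,
            "A_over_AT": c["A"] / c["AT"] if c["AT"] else np.inf,
        })
    return pd.DataFrame(rows)
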