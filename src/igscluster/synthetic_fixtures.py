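"""Synthetic genomes, interaction tables and category tables with planted
ground truth.

The generator emulates the statistical shape of a gene-dense bacterial
chromosome at desk scale: a circular replicon of non-overlapping CDS on
both strands, operons separated by short internal gaps, upstream regions
whose lengths are drawn near the 250 +/- 50 bp regime of restricted
intergenic gaps, Shine-Dalgarno motifs planted at known offsets (default
probability 0.88, offsets peaked near 10 bp), and 175-bp upstream
compositional classes -- T-rich, A-rich and balanced-weak -- whose planted
homopolymer / alternating patches carry the alignment signal that the
clustering stage is meant to recover.

Every emitted file records its generating truth (class per transcription
unit, planted motif and offset, network module and category per gene), so
each pipeline stage can be tested against what was planted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .annotation_io import (GeneRecord, GenomeAnnotation, TranscriptionUnit,
                            write_genbank)

IGS_CLASSES = ("T_rich", "A_rich", "balanced")

# Per-class nucleotide probabilities (order A, T, G, C) and expected planted
# patch counts per 175-bp sequence.  T-rich and A-rich mirror each other;
# the balanced class is weak-nucleotide rich without a strand bias and is
# distinguished by carrying all three patch types with a pronounced
# period-2 alternating-AT character, which gives it an alignment cohesion
# of its own above the mixed-composition background threshold.
CLASS_COMPOSITIONS: dict[str, tuple[float, float, float, float]] = {
    "T_rich": (0.25, 0.45, 0.15, 0.15),
    "A_rich": (0.45, 0.25, 0.15, 0.15),
    "balanced": (0.30, 0.30, 0.20, 0.20),
}
CLASS_PATCH_RATES: dict[str, dict[str, float]] = {
    "T_rich": {"A": 0.0, "T": 3.0, "AT": 0.0},
    "A_rich": {"A": 3.0, "T": 0.0, "AT": 0.0},
    "balanced": {"A": 1.5, "T": 1.5, "AT": 6.0},
}

SDS_PLANT_MOTIF = "AGGAGG"
IGS_LEN = 175


@dataclass(frozen=True)
class FixtureSpec:
    """Knobs of the synthetic genome; defaults are the study conditions."""

    n_genes: int = 60
    operon_fraction: float = 0.5  # fraction of genes living in operons
    operon_sizes: tuple[int, ...] = (2, 3, 4)
    gap_mean: float = 250.0  # upstream intergenic length (bp)
    gap_sd: float = 50.0
    gap_min: int = 210  # keeps the 200-bp window inside the gap
    intra_operon_gap: tuple[int, int] = (5, 20)  # uniform inclusive range
    gene_codons: tuple[int, int] = (30, 100)  # uniform inclusive range
    sds_probability: float = 0.88
    sds_offset_mean: float = 10.0  # peak of the offset distribution
    sds_offset_sd: float = 4.0
    sds_offset_range: tuple[int, int] = (6, 25)
    class_proportions: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    network_within_p: float = 0.9
    network_between_p: float = 0.05
    n_categories: int = 4
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not np.isclose(sum(self.class_proportions), 1.0):
            raise ValueError("class proportions must sum to 1")
        for p in (self.operon_fraction, self.sds_probability,
                  self.network_within_p, self.network_between_p):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class TUTruth:
    tu_id: str
    igs_class: str
    sds_motif: Optional[str]
    sds_offset: Optional[int]
    strand: str
    gene_ids: tuple[str, ...]


@dataclass
class FixtureTruth:
    tus: list[TUTruth] = field(default_factory=list)
    gene_module: dict[str, str] = field(default_factory=dict)
    gene_category: dict[str, str] = field(default_factory=dict)

    def tu_class(self, tu_id: str) -> str:
        for t in self.tus:
            if t.tu_id == tu_id:
                return t.igs_class
        raise KeyError(tu_id)


def _random_seq(rng: np.random.Generator, length: int,
                probs: Sequence[float] = (0.25, 0.25, 0.25, 0.25)) -> str:
    return "".join(rng.choice(list("ATGC"), size=length, p=list(probs)))


def _ct_fill(rng: np.random.Generator, length: int) -> str:
    # C/T only: cannot complete or contain any Shine-Dalgarno (sub)motif
    return "".join(rng.choice(["C", "T"], size=length))


def class_igs_sequence(igs_class: str, rng: np.random.Generator,
                       length: int = IGS_LEN) -> str:
    """One IGS of the given compositional class with planted patches."""
    probs = CLASS_COMPOSITIONS[igs_class]
    seq = list(_random_seq(rng, length, probs))
    for patch_type, rate in CLASS_PATCH_RATES[igs_class].items():
        for _ in range(rng.poisson(rate)):
            plen = int(rng.integers(6, 13))
            start = int(rng.integers(0, length - plen + 1))
            if patch_type == "AT":
                first = rng.choice(["A", "T"])
                other = "T" if first == "A" else "A"
                patch = (first + other) * plen
                patch = patch[:plen]
            else:
                patch = patch_type * plen
            seq[start : start + plen] = list(patch)
    return "".join(seq)


def simulate_igs_set(
    n_per_class: int, rng: np.random.Generator,
    classes: Sequence[str] = IGS_CLASSES, length: int = IGS_LEN,
) -> tuple[list[str], list[str]]:
    """Directly sample labeled class sequences (no genome around them)."""
    seqs, labels = [], []
    for cls in classes:
        for _ in range(n_per_class):
            seqs.append(class_igs_sequence(cls, rng, length))
            labels.append(cls)
    return seqs, labels


def _draw_offset(spec: FixtureSpec, rng: np.random.Generator) -> int:
    lo, hi = spec.sds_offset_range
    p = int(round(rng.normal(spec.sds_offset_mean, spec.sds_offset_sd)))
    return int(np.clip(p, lo, hi))


def _gene_seq(rng: np.random.Generator, n_codons: int) -> str:
    body = _random_seq(rng, 3 * (n_codons - 2))
    return "ATG" + body + "TAA"


def simulate_genome(
    spec: FixtureSpec, rng: Optional[np.random.Generator] = None,
) -> tuple[GenomeAnnotation, list[TranscriptionUnit], FixtureTruth]:
    """Assemble a circular replicon of transcription-unit blocks.

    Each block, written on its coding strand, reads
    ``[pad][planted 175-bp class IGS][SDS motif][C/T spacer][genes]``;
    minus-strand blocks are reverse complemented before insertion.  The
    planted class sequence is exactly what IGS extraction should recover:
    it ends at the first motif nucleotide (or at the TSC when no motif was
    planted, in which case the 25-bp spacer is motif-free C/T).
    """
    rng = np.random.default_rng(spec.rng_seed) if rng is None else rng
    # partition genes into operons and singletons
    sizes: list[int] = []
    remaining = spec.n_genes
    target_operonic = int(round(spec.operon_fraction * spec.n_genes))
    got_operonic = 0
    while got_operonic < target_operonic and remaining > 1:
        s = int(rng.choice(spec.operon_sizes))
        s = min(s, remaining)
        sizes.append(s)
        got_operonic += s
        remaining -= s
    sizes.extend([1] * remaining)

    chrom_parts: list[str] = []
    genes: list[GeneRecord] = []
    tus: list[TranscriptionUnit] = []
    truth = FixtureTruth()
    offset0 = 0
    gene_no = 0
    for tu_no, size in enumerate(sizes):
        tu_id = f"tu{tu_no:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        igs_class = str(rng.choice(IGS_CLASSES, p=list(spec.class_proportions)))
        gap = max(spec.gap_min, int(round(rng.normal(spec.gap_mean, spec.gap_sd))))
        planted_igs = class_igs_sequence(igs_class, rng)
        if rng.random() < spec.sds_probability:
            p = _draw_offset(spec, rng)
            motif = SDS_PLANT_MOTIF
            upstream = (_random_seq(rng, gap - IGS_LEN - p) + planted_igs
                        + motif + _ct_fill(rng, p - len(motif)))
        else:
            p, motif = None, None
            upstream = (_random_seq(rng, gap - IGS_LEN - 25) + planted_igs
                        + _ct_fill(rng, 25))
        block = upstream
        intervals: list[tuple[int, int]] = []
        member_ids: list[str] = []
        for m in range(size):
            if m > 0:
                lo, hi = spec.intra_operon_gap
                block += _random_seq(rng, int(rng.integers(lo, hi + 1)))
            lo, hi = spec.gene_codons
            g_seq = _gene_seq(rng, int(rng.integers(lo, hi + 1)))
            intervals.append((len(block), len(block) + len(g_seq)))
            block += g_seq
            member_ids.append(f"g{gene_no:04d}")
            gene_no += 1
        if strand == "-":
            b = len(block)
            block = str(Seq(block).reverse_complement())
            intervals = [(b - e, b - s) for s, e in intervals]
        for gid, (s, e) in zip(member_ids, intervals):
            genes.append(GeneRecord(gid, strand, offset0 + s, offset0 + e))
        lead = member_ids[0]
        tus.append(TranscriptionUnit(tu_id, tuple(member_ids), lead))
        truth.tus.append(TUTruth(tu_id, igs_class, motif, p, strand,
                                 tuple(member_ids)))
        for gid in member_ids:
            truth.gene_module[gid] = igs_class
        chrom_parts.append(block)
        offset0 += len(block)
    annotation = GenomeAnnotation("synthetic_replicon", "".join(chrom_parts),
                                  "circular", genes)
    return annotation, tus, truth


def write_operon_table(tus: Sequence[TranscriptionUnit], path: str | Path) -> None:
    rows = [(gid, tu.tu_id) for tu in tus if len(tu.member_gene_ids) > 1
            for gid in tu.member_gene_ids]
    pd.DataFrame(rows, columns=["gene_id", "operon_id"]).to_csv(
        path, sep="\t", index=False, header=False)


def simulate_score_table(
    truth: FixtureTruth, rng: np.random.Generator,
    within_p: float = 0.9, between_p: float = 0.05,
    low_score_p: float = 0.1,
) -> pd.DataFrame:
    """Module-structured interaction scores in [0, 1000].

    Within-module pairs exceed the 700 threshold with probability
    ``within_p``; between-module pairs with ``between_p``.  A fraction of
    the remaining pairs receives a sub-threshold score so the table also
    exercises threshold filtering.
    """
    genes = sorted(truth.gene_module)
    rows = []
    for i, a in enumerate(genes):
        for b in genes[i + 1:]:
            same = truth.gene_module[a] == truth.gene_module[b]
            p_edge = within_p if same else between_p
            if rng.random() < p_edge:
                rows.append((a, b, int(rng.integers(701, 1001))))
            elif rng.random() < low_score_p:
                rows.append((a, b, int(rng.integers(0, 701))))
    return pd.DataFrame(rows, columns=["gene1", "gene2", "score"])


def simulate_structureless_score_table(
    genes: Sequence[str], rng: np.random.Generator, edge_p: float = 0.15,
) -> pd.DataFrame:
    """Erdos-Renyi score table with no planted modules (null calibration)."""
    rows = []
    genes = list(genes)
    for i, a in enumerate(genes):
        for b in genes[i + 1:]:
            if rng.random() < edge_p:
                rows.append((a, b, int(rng.integers(701, 1001))))
    return pd.DataFrame(rows, columns=["gene1", "gene2", "score"])


def simulate_category_table(
    truth: FixtureTruth, rng: np.random.Generator,
    enrichment_factor: float = 1.0, target_class: str = "T_rich",
    n_categories: int = 4,
) -> pd.DataFrame:
    """Assign one functional category per gene.

    Background categories are uniform; genes of ``target_class`` draw the
    first category with probability multiplied by ``enrichment_factor``
    (renormalized), planting an over-representation signal.
    """
    if enrichment_factor < 1:
        raise ValueError("enrichment_factor must be >= 1")
    cats = [f"cat{i}" for i in range(n_categories)]
    base = np.full(n_categories, 1.0 / n_categories)
    boosted = base.copy()
    boosted[0] *= enrichment_factor
    boosted /= boosted.sum()
    rows = []
    for gid in sorted(truth.gene_module):
        probs = boosted if truth.gene_module[gid] == target_class else base
        rows.append((gid, str(rng.choice(cats, p=probs))))
    for gid, cat in rows:
        truth.gene_category[gid] = cat
    return pd.DataFrame(rows, columns=["gene_id", "category"])


def write_fixture(spec: FixtureSpec, out_dir: str | Path,
                  enrichment_factor: float = 3.0) -> FixtureTruth:
    """Emit genome.gbk, operons.tsv, scores.tsv, categories.tsv and a truth
    table into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.rng_seed)
    annotation, tus, truth = simulate_genome(spec, rng)
    write_genbank(annotation, out / "genome.gbk")
    write_operon_table(tus, out / "operons.tsv")
    simulate_score_table(truth, rng, spec.network_within_p,
                         spec.network_between_p).to_csv(
        out / "scores.tsv", sep="\t", index=False, header=False)
    simulate_category_table(truth, rng, enrichment_factor,
                            n_categories=spec.n_categories).to_csv(
        out / "categories.tsv", sep="\t", index=False, header=False)
    pd.DataFrame(
        [(t.tu_id, t.igs_class, t.sds_motif or ".", t.sds_offset or ".",
          t.strand, ",".join(t.gene_ids)) for t in truth.tus],
        columns=["tu_id", "igs_class", "sds_motif", "sds_offset", "strand",
                 "gene_ids"],
    ).to_csv(out / "truth.tsv", sep="\t", index=False)
    return truth
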