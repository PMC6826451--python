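"""Intergenic region bookkeeping, Shine-Dalgarno detection and IGS extraction.

The pipeline distinguishes three nested objects per transcription unit:

* IGR  -- from the lead gene's translation start codon (TSC) back to the end
  of the previous coding region *on the same strand*; in gene-dense genomes
  these regions frequently contain reverse complements of genes on the
  opposite strand.
* RIGR -- the strand-agnostic gap between consecutive coding spans;
  overlapping genes contribute a zero-length gap.
* IGS  -- the fixed-length window immediately upstream of the operational
  transcription start site (TSS), taken to be the first nucleotide of the
  Shine-Dalgarno motif when one is found within the ribosome-binding
  search region, and the TSC otherwise.

The common window length is derived from the RIGR length distribution as
round(mean - sd); subtracting one standard deviation trades sample size for
homogeneity of the retained sequences.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from Bio.Seq import Seq

from .annotation_io import GeneRecord, GenomeAnnotation, IGSRecord, TranscriptionUnit

logger = logging.getLogger(__name__)

# Shine-Dalgarno consensus and its admissible subsequences, scanned in
# strictly decreasing length order; the longest motif present wins.
SDS_MOTIFS = ("AGGAGG", "AGGAG", "GGAGG", "GGAG", "GAGG", "AGGA", "GGA", "GAG", "AGG")
DEFAULT_SDS_SEARCH_LEN = 25
DEFAULT_WINDOW_LENGTH = 200


@dataclass(frozen=True)
class Region:
    kind: str  # 'IGR' or 'RIGR'
    anchor: str  # tu_id for IGR, "gene_a..gene_b" for RIGR
    length: int


@dataclass(frozen=True)
class SDSHit:
    """A detected Shine-Dalgarno motif.

    ``offset`` is the distance in bp from the TSC to the motif's first
    nucleotide (the operational TSS): offset 1 means the motif starts at
    the base immediately 5' of the start codon.
    """

    motif: str
    offset: int
    tss: Optional[int] = None  # 0-based genomic position of first motif base

    def __post_init__(self) -> None:
        if self.motif not in SDS_MOTIFS:
            raise ValueError(f"not an admissible SDS motif: {self.motif!r}")
        if self.offset < 1:
            raise ValueError("offset must be >= 1")


def _fetch(annotation: GenomeAnnotation, start: int, length: int) -> Optional[str]:
    """Forward-strand bases [start, start+length), wrapping when circular."""
    n = len(annotation)
    seq = annotation.sequence
    if annotation.is_circular:
        start %= n
        if start + length <= n:
            return seq[start : start + length]
        out = seq[start:]
        while len(out) < length:
            out += seq[: min(n, length - len(out))]
        return out
    if start < 0 or start + length > n:
        return None
    return seq[start : start + length]


def compute_igrs(annotation: GenomeAnnotation,
                 tus: Sequence[TranscriptionUnit]) -> list[Region]:
    """Strand-aware intergenic region length per transcription unit.

    For a ``+`` lead gene the IGR runs from the nearest same-strand coding
    end at or below the TSC up to the TSC; for a ``-`` lead gene the scan is
    mirrored towards higher coordinates.  On circular replicons distances
    are modular, so a strand with a single gene yields the wrap-around
    region; on linear replicons the region is clipped at the edge.
    """
    n = len(annotation)
    by_strand = {"+": [g for g in annotation.genes if g.strand == "+"],
                 "-": [g for g in annotation.genes if g.strand == "-"]}
    regions = []
    for tu in tus:
        lead = annotation.gene(tu.lead_gene_id)
        same = by_strand[lead.strand]
        if lead.strand == "+":
            # distance from a coding end e (exclusive) to the TSC
            dists = [(lead.start - g.end) % n if annotation.is_circular
                     else lead.start - g.end
                     for g in same if g.gene_id != lead.gene_id]
            if annotation.is_circular:
                dists.append((lead.start - lead.end) % n)  # own far side
            dists = [d for d in dists if d >= 0]
            length = min(dists) if dists else lead.start  # to linear edge
        else:
            dists = [(g.start - lead.end) % n if annotation.is_circular
                     else g.start - lead.end
                     for g in same if g.gene_id != lead.gene_id]
            if annotation.is_circular:
                dists.append((lead.start - lead.end) % n)
            dists = [d for d in dists if d >= 0]
            length = min(dists) if dists else n - lead.end
        regions.append(Region("IGR", tu.tu_id, int(length)))
    return regions


def compute_rigrs(annotation: GenomeAnnotation) -> list[Region]:
    """Strand-agnostic gaps between consecutive coding spans.

    Spans are swept in start order with a running maximum end so that
    contained genes never create spurious gaps; overlaps contribute a
    zero-length region.  Circular replicons additionally close the wrap gap
    between the last coding end and the first start.
    """
    genes = annotation.genes
    if len(genes) < 2:
        raise ValueError("need at least two genes to compute RIGRs")
    regions = []
    max_end = genes[0].end
    prev_id = genes[0].gene_id
    for g in genes[1:]:
        gap = max(0, g.start - max_end)
        regions.append(Region("RIGR", f"{prev_id}..{g.gene_id}", gap))
        if g.end >= max_end:
            max_end = g.end
            prev_id = g.gene_id
    if annotation.is_circular:
        gap = max(0, len(annotation) - max_end + genes[0].start)
        regions.append(Region("RIGR", f"{prev_id}..{genes[0].gene_id}", gap))
    return regions


def choose_window_length(rigr_lengths: Sequence[int],
                         override: Optional[int] = None) -> int:
    """Common upstream window length: round(mean - sd) of the RIGR lengths.

    The population standard deviation is used.  ``override`` short-circuits
    the rule (the pipeline default forces 200 bp).
    """
    if override is not None:
        return int(override)
    arr = np.asarray(rigr_lengths, dtype=float)
    if arr.size == 0:
        raise ValueError("empty RIGR length list")
    if np.all(arr == 0):
        raise ValueError("all RIGR lengths are zero")
    return int(round(arr.mean() - arr.std()))


def extract_upstream_window(tu: TranscriptionUnit, annotation: GenomeAnnotation,
                            window_length: int) -> Optional[str]:
    """The ``window_length`` bases immediately 5' of the lead gene's TSC,
    read 5'->3' on the coding strand.

    Crosses coding sequence when the upstream region is shorter than the
    window; wraps through the origin on circular replicons.  Returns None
    (caller skips the record) when a linear replicon has too little
    upstream sequence.
    """
    lead = annotation.gene(tu.lead_gene_id)
    if lead.strand == "+":
        raw = _fetch(annotation, lead.start - window_length, window_length)
        return raw
    raw = _fetch(annotation, lead.end, window_length)
    if raw is None:
        return None
    return str(Seq(raw).reverse_complement())


def detect_sds(window: str, search_len: int = DEFAULT_SDS_SEARCH_LEN) -> Optional[SDSHit]:
    """Scan the ribosome-binding region for a Shine-Dalgarno motif.

    Motifs are tried in strictly decreasing length order (6, 5, 4, 3 bp);
    a motif counts when its first nucleotide lies within the last
    ``search_len`` bases of the window (i.e. within ``search_len`` bp of
    the TSC).  The longest motif wins; among hits of the winning length the
    one closest to the TSC is returned.
    """
    if len(window) < search_len:
        raise ValueError("window shorter than the SDS search region")
    w = window.upper()
    lw = len(w)
    lo = lw - search_len  # motif first nucleotide must be at index >= lo
    for length in (6, 5, 4, 3):
        best_start = -1
        best_motif = None
        for motif in SDS_MOTIFS:
            if len(motif) != length:
                continue
            start = w.rfind(motif)  # last occurrence = closest to the TSC
            if start >= lo and start > best_start:
                best_start, best_motif = start, motif
        if best_motif is not None:
            return SDSHit(best_motif, lw - best_start)
    return None


def extract_igs(window: str, sds: Optional[SDSHit], window_length: int,
                search_len: int = DEFAULT_SDS_SEARCH_LEN) -> str:
    """Cut the fixed-length IGS out of the upstream window.

    The IGS is the ``window_length - search_len`` bases immediately 5' of
    the TSS (first SDS nucleotide), or of the TSC when no SDS was found.
    """
    if len(window) != window_length:
        raise ValueError("window length mismatch")
    igs_len = window_length - search_len
    if sds is None:
        return window[-igs_len:]
    stop = window_length - sds.offset
    return window[stop - igs_len : stop]


def coding_mask(annotation: GenomeAnnotation) -> np.ndarray:
    """Boolean array over the replicon: True where any CDS (either strand)
    covers the position."""
    mask = np.zeros(len(annotation), dtype=bool)
    for g in annotation.genes:
        mask[g.start : g.end] = True
    return mask


def coding_fraction(start: int, end: int, annotation: GenomeAnnotation,
                    mask: Optional[np.ndarray] = None) -> float:
    """Fraction of [start, end) positions overlapped by coding sequence on
    either strand (modular on circular replicons)."""
    if mask is None:
        mask = coding_mask(annotation)
    n = len(annotation)
    if end <= n and start >= 0:
        return float(mask[start:end].mean())
    idx = np.arange(start, end) % n
    return float(mask[idx].mean())


@dataclass
class ExtractionLog:
    n_tus: int = 0
    n_igs: int = 0
    n_sds: int = 0
    n_skipped: int = 0

    @property
    def sds_fraction(self) -> float:
        return self.n_sds / self.n_igs if self.n_igs else float("nan")


def extract_igs_records(
    annotation: GenomeAnnotation,
    tus: Sequence[TranscriptionUnit],
    window_length: int = DEFAULT_WINDOW_LENGTH,
    search_len: int = DEFAULT_SDS_SEARCH_LEN,
) -> tuple[list[IGSRecord], ExtractionLog]:
    """Run window extraction, SDS detection and IGS cutting for every
    transcription unit; returns the records plus a count log."""
    if window_length <= search_len:
        raise ValueError("window_length must exceed the SDS search region")
    mask = coding_mask(annotation)
    n = len(annotation)
    igs_len = window_length - search_len
    records: list[IGSRecord] = []
    log = ExtractionLog(n_tus=len(tus))
    for tu in tus:
        window = extract_upstream_window(tu, annotation, window_length)
        if window is None:
            warnings.warn(
                f"TU {tu.tu_id}: fewer than {window_length} bp upstream on "
                "linear replicon; record skipped", stacklevel=2)
            log.n_skipped += 1
            continue
        sds = detect_sds(window, search_len)
        seq = extract_igs(window, sds, window_length, search_len)
        lead = annotation.gene(tu.lead_gene_id)
        shift = 0 if sds is None else sds.offset
        if lead.strand == "+":
            end = lead.start - shift
            start = end - igs_len
            tss = lead.start - shift if sds is not None else None
        else:
            start = lead.end + shift
            end = start + igs_len
            tss = lead.end - 1 + shift if sds is not None else None
        if annotation.is_circular:
            start %= n
            end = start + igs_len
        if sds is not None:
            sds = SDSHit(sds.motif, sds.offset, tss)
            log.n_sds += 1
        records.append(IGSRecord(
            tu_id=tu.tu_id,
            sequence=seq,
            sds_motif=sds.motif if sds else None,
            sds_offset=sds.offset if sds else None,
            coding_fraction=coding_fraction(start, end, annotation, mask),
            start=start,
            end=end,
            strand=lead.strand,
        ))
        log.n_igs += 1
    return records, log
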