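"""Genome annotation and sequence-set I/O.

All coordinates inside the package are 0-based half-open intervals on the
forward strand of a single replicon.  GenBank and GFF3 use 1-based inclusive
coordinates; the conversion happens here and nowhere else.  Strand logic
(reverse complementation, transcription order) is localized to the
extraction module.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord
import pandas as pd

logger = logging.getLogger(__name__)

START_CODONS = ("ATG", "GTG", "TTG", "CTG", "ATT", "ATA", "ATC")


@dataclass(frozen=True)
class GeneRecord:
    """One protein-coding gene on the replicon.

    ``start``/``end`` delimit the coding span (0-based half-open, forward
    strand).  The translation start codon (TSC) position is the first base
    of the start codon read on the coding strand: ``start`` for ``+`` genes
    and ``end - 1`` for ``-`` genes.
    """

    gene_id: str
    strand: str  # '+' or '-'
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.end <= self.start:
            raise ValueError(f"empty span for gene {self.gene_id}")

    @property
    def tsc(self) -> int:
        """0-based genomic position of the first base of the start codon."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class GenomeAnnotation:
    """A single replicon: sequence, topology and its ordered gene records."""

    replicon_id: str
    sequence: str
    topology: str = "circular"  # or 'linear'
    genes: list[GeneRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.topology not in ("circular", "linear"):
            raise ValueError(f"invalid topology {self.topology!r}")
        self.genes = sorted(self.genes, key=lambda g: (g.start, g.end))
        ids = [g.gene_id for g in self.genes]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate gene ids in annotation")
        n = len(self.sequence)
        for g in self.genes:
            if not (0 <= g.start < n and 0 < g.end <= n):
                raise ValueError(
                    f"gene {g.gene_id} span {g.span} outside replicon of length {n}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def is_circular(self) -> bool:
        return self.topology == "circular"

    def gene(self, gene_id: str) -> GeneRecord:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def start_codon(self, gene: GeneRecord) -> str:
        """Start codon read 5'->3' on the coding strand."""
        if gene.strand == "+":
            return self.sequence[gene.start : gene.start + 3]
        triplet = self.sequence[gene.end - 3 : gene.end]
        return str(Seq(triplet).reverse_complement())


@dataclass(frozen=True)
class TranscriptionUnit:
    """A co-transcribed gene group (operon) or a singleton gene.

    The lead gene is the strand-wise 5'-most member: it owns the single
    upstream regulatory region shared by the whole unit.
    """

    tu_id: str
    member_gene_ids: tuple[str, ...]
    lead_gene_id: str


@dataclass(frozen=True)
class IGSRecord:
    """One equal-length intergenic sequence (IGS).

    The sequence is read 5'->3' on the coding strand of the lead gene and
    ends immediately upstream of the transcription start site -- the first
    nucleotide of the detected Shine-Dalgarno motif, or the translation
    start codon when no motif was found.
    """

    tu_id: str
    sequence: str
    sds_motif: Optional[str]
    sds_offset: Optional[int]
    coding_fraction: float
    start: int
    end: int
    strand: str


def read_genbank(path: str | Path, atg_only: bool = False) -> GenomeAnnotation:
    """Read one replicon from a GenBank flat file.

    One ``GeneRecord`` is emitted per simple-location CDS feature; compound
    (joined) locations are skipped with a warning.  With ``atg_only`` genes
    whose annotated start codon is not ATG are dropped.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "genbank"))
    if len(records) == 0:
        raise ValueError(f"no GenBank records found in {path}")
    if len(records) > 1:
        raise ValueError(
            f"{path} contains {len(records)} replicons; run once per replicon"
        )
    rec = records[0]
    topology = rec.annotations.get("topology", "circular")
    genes: list[GeneRecord] = []
    seen: set[str] = set()
    n_cds = 0
    for feat in rec.features:
        if feat.type != "CDS":
            continue
        n_cds += 1
        loc = feat.location
        if len(getattr(loc, "parts", [loc])) > 1:
            warnings.warn(
                f"skipping CDS with compound location at {loc}", stacklevel=2
            )
            continue
        strand = "-" if loc.strand == -1 else "+"
        gid = _cds_identifier(feat, seen, fallback=f"cds{n_cds:05d}")
        seen.add(gid)
        genes.append(GeneRecord(gid, strand, int(loc.start), int(loc.end)))
    if not genes:
        raise ValueError(f"no CDS features found in {path}")
    ann = GenomeAnnotation(rec.id or path.stem, str(rec.seq).upper(), topology, genes)
    if atg_only:
        ann.genes = [g for g in ann.genes if ann.start_codon(g) == "ATG"]
    return ann


def _cds_identifier(feat: SeqFeature, seen: set[str], fallback: str) -> str:
    for key in ("locus_tag", "gene", "protein_id"):
        vals = feat.qualifiers.get(key)
        if vals and vals[0] not in seen:
            return vals[0]
    return fallback


def read_fasta_gff3(fasta_path: str | Path, gff_path: str | Path,
                    topology: str = "circular") -> GenomeAnnotation:
    """Alternate reader: replicon FASTA plus GFF3 with CDS features."""
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"{fasta_path} must contain exactly one sequence")
    rec = records[0]
    df = pd.read_csv(
        gff_path, sep="\t", comment="#", header=None,
        names=["seqid", "source", "type", "start", "end",
               "score", "strand", "phase", "attributes"],
    )
    cds = df[df["type"] == "CDS"]
    if cds.empty:
        raise ValueError(f"no CDS features in {gff_path}")
    genes = []
    seen: set[str] = set()
    for i, row in enumerate(cds.itertuples(index=False)):
        gid = _gff_identifier(row.attributes, seen, fallback=f"cds{i + 1:05d}")
        seen.add(gid)
        # GFF3 1-based inclusive -> 0-based half-open
        genes.append(GeneRecord(gid, row.strand, int(row.start) - 1, int(row.end)))
    return GenomeAnnotation(rec.id, str(rec.seq).upper(), topology, genes)


def _gff_identifier(attributes: str, seen: set[str], fallback: str) -> str:
    fields = dict(
        kv.split("=", 1) for kv in attributes.split(";") if "=" in kv
    )
    for key in ("locus_tag", "ID", "Name"):
        if key in fields and fields[key] not in seen:
            return fields[key]
    return fallback


def read_operon_table(path: str | Path,
                      annotation: GenomeAnnotation) -> list[TranscriptionUnit]:
    """Group annotated genes into transcription units from an operon table.

    The table is a two-column TSV (``gene_id``, ``operon_id``; header
    optional).  Annotated genes absent from the table become singleton
    units.  Table rows naming unknown genes are skipped with a warning; an
    operon whose members lie on both strands is an error.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "operon_id"],
                     dtype=str, comment="#")
    if len(df) and tuple(df.iloc[0]) == ("gene_id", "operon_id"):
        df = df.iloc[1:]
    known = {g.gene_id: g for g in annotation.genes}
    groups: dict[str, list[str]] = {}
    assigned: set[str] = set()
    for row in df.itertuples(index=False):
        if row.gene_id not in known:
            warnings.warn(
                f"operon table gene {row.gene_id!r} not in annotation; row skipped",
                stacklevel=2,
            )
            continue
        groups.setdefault(row.operon_id, []).append(row.gene_id)
        assigned.add(row.gene_id)
    tus = []
    for op_id, members in groups.items():
        tus.append(make_transcription_unit(op_id, members, annotation))
    for g in annotation.genes:
        if g.gene_id not in assigned:
            tus.append(TranscriptionUnit(g.gene_id, (g.gene_id,), g.gene_id))
    return tus


def make_transcription_unit(tu_id: str, member_gene_ids: Iterable[str],
                            annotation: GenomeAnnotation) -> TranscriptionUnit:
    members = [annotation.gene(gid) for gid in member_gene_ids]
    strands = {g.strand for g in members}
    if len(strands) > 1:
        raise ValueError(f"operon {tu_id} spans both strands")
    strand = strands.pop()
    if strand == "+":
        ordered = sorted(members, key=lambda g: g.start)
    else:
        ordered = sorted(members, key=lambda g: g.end, reverse=True)
    return TranscriptionUnit(tu_id, tuple(g.gene_id for g in ordered),
                             ordered[0].gene_id)


def write_igs_fasta(records: list[IGSRecord], path: str | Path) -> None:
    """Write IGS records as FASTA with ``|``-delimited metadata headers."""
    lengths = {len(r.sequence) for r in records}
    if len(lengths) > 1:
        raise ValueError(f"mixed IGS lengths {sorted(lengths)}")
    seq_records = []
    for r in records:
        header = (
            f"{r.tu_id}|sds={r.sds_motif or '.'}|offset={r.sds_offset or '.'}"
            f"|coding_fraction={r.coding_fraction:.6f}"
            f"|span={r.start}-{r.end}|strand={r.strand}"
        )
        seq_records.append(SeqRecord(Seq(r.sequence), id=header, description=""))
    SeqIO.write(seq_records, str(path), "fasta")


def read_igs_fasta(path: str | Path) -> list[IGSRecord]:
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        meta = dict(kv.split("=", 1) for kv in parts[1:])
        span = meta["span"].split("-")
        records.append(IGSRecord(
            tu_id=parts[0],
            sequence=str(rec.seq).upper(),
            sds_motif=None if meta["sds"] == "." else meta["sds"],
            sds_offset=None if meta["offset"] == "." else int(meta["offset"]),
            coding_fraction=float(meta["coding_fraction"]),
            start=int(span[0]),
            end=int(span[1]),
            strand=meta["strand"],
        ))
    lengths = {len(r.sequence) for r in records}
    if len(lengths) > 1:
        raise ValueError(f"mixed IGS lengths in {path}: {sorted(lengths)}")
    return records


def write_genbank(annotation: GenomeAnnotation, path: str | Path) -> None:
    """Serialize an annotation back to a GenBank flat file."""
    rec = SeqRecord(Seq(annotation.sequence), id=annotation.replicon_id,
                    name=annotation.replicon_id[:16],
                    description="synthetic replicon")
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = annotation.topology
    for g in annotation.genes:
        loc = FeatureLocation(g.start, g.end, strand=1 if g.strand == "+" else -1)
        feat = SeqFeature(loc, type="CDS",
                          qualifiers={"locus_tag": [g.gene_id]})
        rec.features.append(feat)
    SeqIO.write([rec], str(path), "genbank")
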