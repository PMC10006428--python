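"""Domain types and readers/writers for the external formats the pipeline touches.

All genomic intervals inside the package are 0-based half-open on the forward
strand; 1-based inclusive coordinates exist only at the GFF3 / CX-report file
boundary, where :func:`gff_to_internal` / :func:`internal_to_gff` convert (an
involution, tested as such).

Readers are strict: a malformed row raises :class:`~gymnome.errors.FormatError`
carrying the file path and line number instead of being skipped.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError, ValidationError

DNA_ALPHABET = set("ACGTN")
CONTEXTS = ("CG", "CHG", "CHH")

# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeSequence:
    """A named DNA sequence (assembly contig/chromosome or spike-in)."""

    id: str
    residues: str

    def __post_init__(self):
        if not self.id:
            raise ValidationError("sequence id must be non-empty")
        if len(self.residues) < 1:
            raise ValidationError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - DNA_ALPHABET
        if bad:
            raise ValidationError(
                f"sequence {self.id!r} contains non-DNA characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True, order=True)
class Interval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise ValidationError("interval chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene with the exon chain of its representative (longest) transcript."""

    gene_id: str
    interval: Interval
    exons: tuple[Interval, ...]
    biotype: str = "protein_coding"

    def __post_init__(self):
        if len(self.exons) < 1:
            raise ValidationError(f"gene {self.gene_id!r} has no exons")
        prev_end = None
        for ex in self.exons:
            if ex.chrom != self.interval.chrom or ex.strand != self.interval.strand:
                raise ValidationError(
                    f"gene {self.gene_id!r}: exon on different chrom/strand"
                )
            if ex.start < self.interval.start or ex.end > self.interval.end:
                raise ValidationError(
                    f"gene {self.gene_id!r}: exon {ex.start}-{ex.end} outside "
                    f"gene span {self.interval.start}-{self.interval.end}"
                )
            if prev_end is not None and ex.start < prev_end:
                raise ValidationError(
                    f"gene {self.gene_id!r}: exons unsorted or overlapping"
                )
            prev_end = ex.end

    @property
    def introns(self) -> tuple[Interval, ...]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(Interval(a.chrom, a.end, b.start, a.strand))
        return tuple(out)

    @property
    def spliced_length(self) -> int:
        return sum(len(e) for e in self.exons)


@dataclass(frozen=True)
class CytosineRecord:
    """One cytosine's strand, context and methylated/total read counts.

    The atom of all methylome statistics: per-site methylation level is
    count_m / count_total, and every aggregate pools counts before dividing.
    """

    chrom: str
    pos: int  # 1-based, as in the CX report
    strand: str
    context: str
    count_m: int
    count_total: int

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValidationError(f"invalid strand {self.strand!r}")
        if self.context not in CONTEXTS:
            raise ValidationError(f"invalid context {self.context!r}")
        if not (0 <= self.count_m <= self.count_total):
            raise ValidationError(
                f"invalid counts m={self.count_m} total={self.count_total}"
            )
        if self.pos < 1:
            raise ValidationError(f"invalid 1-based position {self.pos}")

    @property
    def covered(self) -> bool:
        return self.count_total > 0

    @property
    def level(self) -> float:
        if self.count_total == 0:
            raise ValidationError("level undefined at zero coverage")
        return self.count_m / self.count_total


@dataclass(frozen=True)
class BlastHitRow:
    """One tabular alignment row annotated with species and database class."""

    query_id: str
    subject_id: str
    species: str
    db_class: str  # out / mid / in
    bitscore: float
    evalue: float

    def __post_init__(self):
        if self.db_class not in ("out", "mid", "in"):
            raise ValidationError(f"invalid db_class {self.db_class!r}")
        if self.bitscore < 0 or self.evalue < 0:
            raise ValidationError("bitscore and evalue must be >= 0")


@dataclass(frozen=True)
class KsRecord:
    """Synonymous-substitution rate (Ks) of one gene pair."""

    pair_id: str
    ks: float

    def __post_init__(self):
        import math

        if not math.isfinite(self.ks) or self.ks < 0:
            raise ValidationError(f"invalid Ks {self.ks} for {self.pair_id!r}")


@dataclass(frozen=True)
class ExpressionRecord:
    """TPM of one gene in one sample."""

    gene_id: str
    sample_id: str
    tpm: float

    def __post_init__(self):
        import math

        if not math.isfinite(self.tpm) or self.tpm < 0:
            raise ValidationError(f"invalid TPM {self.tpm} for {self.gene_id!r}")


# ---------------------------------------------------------------------------
# coordinate conversion
# ---------------------------------------------------------------------------


def gff_to_internal(start_1based: int, end_inclusive: int) -> tuple[int, int]:
    """GFF3 1-based inclusive -> internal 0-based half-open."""
    return start_1based - 1, end_inclusive


def internal_to_gff(start: int, end: int) -> tuple[int, int]:
    """Internal 0-based half-open -> GFF3 1-based inclusive (involution)."""
    return start + 1, end


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read a (possibly wrapped) multi-record FASTA, uppercasing residues."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError("no FASTA records found", path=str(path))
    out: list[GenomeSequence] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r}", path=str(path))
        seen.add(rec.id)
        out.append(GenomeSequence(rec.id, str(rec.seq).upper()))
    return out


def write_fasta(seqs: Iterable[GenomeSequence], path: str | Path, width: int = 60) -> None:
    records = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# CX report (Bismark-style per-cytosine table)
# ---------------------------------------------------------------------------


def read_cx_report(path: str | Path) -> list[CytosineRecord]:
    """Read a 7-column CX report: chrom, pos, strand, count_m, count_um, context, tri.

    Zero-coverage rows are retained (they carry the genome-wide cytosine
    census); downstream level computations exclude them via ``covered``.
    """
    path = Path(path)
    out: list[CytosineRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(
                    f"expected >= 6 tab-separated columns, got {len(fields)}",
                    path=str(path), line=lineno,
                )
            chrom, pos_s, strand, m_s, um_s, context = fields[:6]
            try:
                pos, m, um = int(pos_s), int(m_s), int(um_s)
            except ValueError as exc:
                raise FormatError(f"non-integer field: {exc}", path=str(path), line=lineno)
            if m < 0 or um < 0:
                raise FormatError(
                    f"negative count (m={m}, um={um})", path=str(path), line=lineno
                )
            if context not in CONTEXTS:
                raise FormatError(
                    f"unknown context token {context!r}", path=str(path), line=lineno
                )
            try:
                out.append(CytosineRecord(chrom, pos, strand, context, m, m + um))
            except ValidationError as exc:
                raise FormatError(str(exc), path=str(path), line=lineno)
    return out


def write_cx_report(records: Iterable[CytosineRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            tri = r.context if len(r.context) == 3 else r.context + "N"
            fh.write(
                f"{r.chrom}\t{r.pos}\t{r.strand}\t{r.count_m}\t"
                f"{r.count_total - r.count_m}\t{r.context}\t{tri}\n"
            )


# ---------------------------------------------------------------------------
# GFF3 gene models
# ---------------------------------------------------------------------------


def read_gff_genes(path: str | Path) -> list[GeneModel]:
    """Read gene models from GFF3, keeping the longest (spliced) transcript per gene.

    Coordinates are converted to the internal 0-based half-open convention.
    """
    import gffutils

    path = Path(path)
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        if "ID" not in gene.attributes:
            raise FormatError(
                f"gene feature at {gene.seqid}:{gene.start} lacks ID attribute",
                path=str(path),
            )
        gene_id = gene.attributes["ID"][0]
        gstart, gend = gff_to_internal(gene.start, gene.end)
        gene_iv = Interval(gene.seqid, gstart, gend, gene.strand)
        best: tuple[int, str, tuple[Interval, ...]] | None = None
        transcripts = list(db.children(gene, featuretype=("mRNA", "transcript")))
        parents = transcripts if transcripts else [gene]
        for tx in parents:
            exons = []
            for ex in db.children(tx, featuretype="exon", order_by="start"):
                estart, eend = gff_to_internal(ex.start, ex.end)
                if estart < gstart or eend > gend:
                    raise FormatError(
                        f"exon {ex.seqid}:{ex.start}-{ex.end} outside gene "
                        f"{gene_id!r} span",
                        path=str(path),
                    )
                exons.append(Interval(ex.seqid, estart, eend, gene.strand))
            if not exons:
                continue
            spliced = sum(len(e) for e in exons)
            tx_id = tx.attributes.get("ID", [tx.id])[0]
            # longest spliced transcript wins; ties broken by transcript id
            if best is None or spliced > best[0] or (
                spliced == best[0] and tx_id < best[1]
            ):
                best = (spliced, tx_id, tuple(exons))
        if best is None:
            raise FormatError(f"gene {gene_id!r} has no exons", path=str(path))
        biotype = gene.attributes.get("biotype", ["protein_coding"])[0]
        genes.append(GeneModel(gene_id, gene_iv, best[2], biotype))
    return genes


# ---------------------------------------------------------------------------
# BLAST tabular (outfmt 6) + species map
# ---------------------------------------------------------------------------


def read_species_map(path: str | Path) -> dict[str, str]:
    """Read a 2-column TSV mapping subject id -> species label."""
    path = Path(path)
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError("expected 2 columns", path=str(path), line=lineno)
            out[fields[0]] = fields[1]
    return out


def read_blast_tab(
    path: str | Path,
    species_map: dict[str, str] | str | Path,
    db_class: str,
    evalue_cutoff: float = 1e-5,
) -> list[BlastHitRow]:
    """Read 12-column BLAST outfmt-6, annotate with species/db, filter by e-value.

    Every subject id must resolve through the species map ("one hit per
    species" downstream cannot be enforced otherwise).
    """
    path = Path(path)
    if not isinstance(species_map, dict):
        species_map = read_species_map(species_map)
    out: list[BlastHitRow] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise FormatError(
                    f"expected 12 columns, got {len(fields)}",
                    path=str(path), line=lineno,
                )
            qseqid, sseqid = fields[0], fields[1]
            try:
                evalue = float(fields[10])
                bitscore = float(fields[11])
            except ValueError as exc:
                raise FormatError(f"bad numeric field: {exc}", path=str(path), line=lineno)
            if evalue > evalue_cutoff:
                continue
            if sseqid not in species_map:
                raise FormatError(
                    f"subject {sseqid!r} missing from species map",
                    path=str(path), line=lineno,
                )
            out.append(
                BlastHitRow(qseqid, sseqid, species_map[sseqid], db_class, bitscore, evalue)
            )
    return out


def write_blast_tab(rows: Iterable[BlastHitRow], path: str | Path) -> None:
    """Write minimal outfmt-6 rows (alignment geometry columns are placeholders)."""
    with open(path, "w") as fh:
        for r in rows:
            fh.write(
                f"{r.query_id}\t{r.subject_id}\t100.0\t100\t0\t0\t1\t100\t1\t100\t"
                f"{r.evalue:.3g}\t{r.bitscore:.1f}\n"
            )


# ---------------------------------------------------------------------------
# BED and simple TSV tables
# ---------------------------------------------------------------------------


def write_bed(intervals: Iterable[Interval], path: str | Path,
              names: Sequence[str] | None = None,
              scores: Sequence[float] | None = None) -> None:
    intervals = list(intervals)
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else f"region{i + 1}"
            score = scores[i] if scores is not None else 0
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")


def read_bed(path: str | Path) -> list[Interval]:
    path = Path(path)
    out: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError("expected >= 3 columns", path=str(path), line=lineno)
            strand = fields[5] if len(fields) >= 6 else "."
            try:
                out.append(Interval(fields[0], int(fields[1]), int(fields[2]), strand))
            except (ValueError, ValidationError) as exc:
                raise FormatError(str(exc), path=str(path), line=lineno)
    return out


def read_ks_table(path: str | Path) -> list[KsRecord]:
    """Read a headered TSV with columns pair_id, ks."""
    path = Path(path)
    out: list[KsRecord] = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "ks" not in reader.fieldnames:
            raise FormatError("missing header with 'ks' column", path=str(path))
        for lineno, row in enumerate(reader, start=2):
            try:
                out.append(KsRecord(row.get("pair_id", f"pair{lineno}"), float(row["ks"])))
            except (ValueError, ValidationError) as exc:
                raise FormatError(str(exc), path=str(path), line=lineno)
    return out


def write_ks_table(records: Iterable[KsRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("pair_id\tks\n")
        for r in records:
            fh.write(f"{r.pair_id}\t{r.ks:.6g}\n")


def read_expression_table(path: str | Path) -> list[ExpressionRecord]:
    """Read a long-format TSV with columns gene_id, sample_id, tpm."""
    path = Path(path)
    out: list[ExpressionRecord] = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"gene_id", "sample_id", "tpm"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise FormatError(
                f"missing header columns {sorted(required)}", path=str(path)
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                out.append(
                    ExpressionRecord(row["gene_id"], row["sample_id"], float(row["tpm"]))
                )
            except (ValueError, ValidationError) as exc:
                raise FormatError(str(exc), path=str(path), line=lineno)
    return out
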