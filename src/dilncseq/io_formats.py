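"""Readers and writers for the formats the pipeline touches.

FASTA and FASTQ parsing is delegated to Biopython, wrapped so that malformed
input produces errors that name the offending line or record.  GFF3 is read
through :mod:`gffutils` (in-memory database) and converted to the internal
0-based half-open convention at the boundary.  BED6 and TSV tables are plain
text written directly.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .intervals import STRANDS, GeneModel, GenomicInterval


class ParseError(ValueError):
    """Malformed input file; message names the file and location."""


FASTA_ALPHABET = set("ACGTN")


class _LineCountingHandle:
    """File-handle wrapper that remembers the last line number read."""

    def __init__(self, handle):
        self._handle = handle
        self.lineno = 0

    def __iter__(self):
        for line in self._handle:
            self.lineno += 1
            yield line

    def readline(self, *args):
        line = self._handle.readline(*args)
        if line:
            self.lineno += 1
        return line

    def read(self, *args):
        return self._handle.read(*args)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into ``{name: SEQUENCE}`` (upper-cased).

    Sequences must be over ``{A,C,G,T,N}``; empty records or malformed
    headers raise :class:`ParseError` naming the line.
    """
    path = Path(path)
    genome: dict[str, str] = {}
    with open(path) as raw:
        counted = _LineCountingHandle(raw)
        try:
            records = SeqIO.parse(counted, "fasta")
        except ValueError as exc:
            raise ParseError(
                f"{path}: malformed FASTA near line {max(counted.lineno, 1)}: {exc}"
            ) from exc
        for record in records:
            seq = str(record.seq).upper()
            if not record.id:
                raise ParseError(
                    f"{path}: malformed header near line {counted.lineno}"
                )
            if not seq:
                raise ParseError(
                    f"{path}: empty record {record.id!r} near line {counted.lineno}"
                )
            bad = set(seq) - FASTA_ALPHABET
            if bad:
                raise ParseError(
                    f"{path}: record {record.id!r} contains non-DNA characters "
                    f"{sorted(bad)} near line {counted.lineno}"
                )
            if record.id in genome:
                raise ParseError(f"{path}: duplicate sequence name {record.id!r}")
            genome[record.id] = seq
    if not genome:
        # distinguish "no records" from a file of garbage that SeqIO skipped
        with open(path) as handle:
            for lineno, line in enumerate(handle, 1):
                if line.strip():
                    raise ParseError(
                        f"{path}: no FASTA records parsed; first non-blank "
                        f"content at line {lineno}"
                    )
    return genome


def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as out:
        for name, seq in genome.items():
            out.write(f">{name}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Stream ``(read_id, sequence, quality)`` tuples from a 4-line FASTQ.

    Truncated records or sequence/quality length mismatches raise
    :class:`ParseError` carrying the record index.
    """
    path = Path(path)
    with open(path) as handle:
        record_index = 0
        try:
            for title, seq, qual in FastqGeneralIterator(handle):
                record_index += 1
                yield title.split()[0], seq.upper(), qual
        except ValueError as exc:
            raise ParseError(
                f"{path}: malformed FASTQ at record {record_index + 1}: {exc}"
            ) from exc


def write_fastq(reads: Iterable[tuple[str, str, str]], path: str | Path) -> int:
    """Write ``(read_id, sequence, quality)`` tuples; returns record count."""
    n = 0
    with open(path, "w") as out:
        for read_id, seq, qual in reads:
            out.write(f"@{read_id}\n{seq}\n+\n{qual}\n")
            n += 1
    return n


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene and exon features from GFF3 into :class:`GeneModel` objects.

    GFF3 1-based inclusive coordinates are converted to 0-based half-open.
    Exon parentage is resolved through ID/Parent attributes (transcript-level
    indirection allowed).  Genes must carry an explicit ``+``/``-`` strand.
    """
    path = Path(path)
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        if gene.strand not in STRANDS:
            raise ParseError(
                f"{path}: gene {gene.id} has strand {gene.strand!r}; "
                "gene features require '+' or '-'"
            )
        span = GenomicInterval(gene.seqid, gene.start - 1, gene.end, gene.strand)
        exons = []
        for exon in db.children(gene.id, featuretype="exon", order_by="start"):
            iv = GenomicInterval(exon.seqid, exon.start - 1, exon.end, exon.strand)
            if iv.start < span.start or iv.end > span.end:
                raise ParseError(
                    f"{path}: exon {iv.start}-{iv.end} outside gene "
                    f"{gene.id} span {span.start}-{span.end}"
                )
            exons.append(iv)
        genes.append(GeneModel(gene.id, span, tuple(exons)))
    return genes


def write_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write GeneModels as gene + exon features (1-based inclusive on disk)."""
    with open(path, "w") as out:
        out.write("##gff-version 3\n")
        for gene in genes:
            s = gene.span
            out.write(
                f"{s.chrom}\tdilncseq\tgene\t{s.start + 1}\t{s.end}\t.\t"
                f"{s.strand}\t.\tID={gene.gene_id}\n"
            )
            for i, exon in enumerate(gene.exons, 1):
                out.write(
                    f"{exon.chrom}\tdilncseq\texon\t{exon.start + 1}\t{exon.end}"
                    f"\t.\t{exon.strand}\t.\tID={gene.gene_id}.exon{i};"
                    f"Parent={gene.gene_id}\n"
                )


def write_bed(items: Iterable, path: str | Path) -> int:
    """Write BED6 lines for objects carrying a GenomicInterval.

    Accepts GenomicIntervals directly, or objects with ``interval`` plus
    optional ``read_id``/``n_candidates`` attributes (alignments).  Returns
    the number of lines written.
    """
    n = 0
    with open(path, "w") as out:
        for item in items:
            if isinstance(item, GenomicInterval):
                iv, name, score = item, ".", 0
            else:
                iv = item.interval
                name = getattr(item, "read_id", ".")
                score = getattr(item, "n_candidates", 0)
            out.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")
            n += 1
    return n


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED (>= 3 columns; strand from column 6, '+' if absent)."""
    out = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: fewer than 3 BED columns")
            strand = fields[5] if len(fields) >= 6 else "+"
            out.append(
                GenomicInterval(fields[0], int(fields[1]), int(fields[2]), strand)
            )
    return out


def write_counts_tsv(table: pd.DataFrame, path: str | Path) -> None:
    """Write a rectangular table as TSV with deterministic row order.

    Rows are sorted by locus then library identifier when those columns are
    present; ragged input (non-DataFrame rows of unequal length) is rejected.
    """
    if not isinstance(table, pd.DataFrame):
        rows = list(table)
        if not rows:
            raise ValueError("empty table: need at least a header row")
        header, *body = rows
        widths = {len(r) for r in rows}
        if len(widths) > 1:
            raise ValueError(f"ragged table rows: widths {sorted(widths)}")
        table = pd.DataFrame(body, columns=header)
    sort_cols = [c for c in ("locus_id", "library_id") if c in table.columns]
    if sort_cols:
        table = table.sort_values(sort_cols, kind="mergesort")
    table.to_csv(path, sep="\t", index=False)


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


@dataclass(frozen=True)
class SampleSheetEntry:
    """One sequencing library in the experimental design."""

    library_id: str
    fraction: str  # "input" or "IP"
    polymerase: str  # "polII" or "polIII"
    condition: str  # identifier of the cleaved locus, or "none"
    replicate: int
    fastq_path: str

    def __post_init__(self) -> None:
        if self.fraction not in ("input", "IP"):
            raise ValueError(f"fraction must be input/IP, got {self.fraction!r}")
        if self.polymerase not in ("polII", "polIII"):
            raise ValueError(f"polymerase must be polII/polIII, got {self.polymerase!r}")
        if self.replicate < 1:
            raise ValueError("replicate must be a positive integer")


SAMPLE_SHEET_COLUMNS = [
    "library_id",
    "fraction",
    "polymerase",
    "condition",
    "replicate",
    "fastq_path",
]


def read_sample_sheet(path: str | Path) -> list[SampleSheetEntry]:
    """Read the library design TSV and validate its pairing invariants.

    Library ids must be unique and every IP library must have a same
    (polymerase, condition, replicate) input library.
    """
    entries: list[SampleSheetEntry] = []
    with open(path) as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        missing = set(SAMPLE_SHEET_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise ParseError(f"{path}: missing sample sheet columns {sorted(missing)}")
        for row in reader:
            entries.append(
                SampleSheetEntry(
                    library_id=row["library_id"],
                    fraction=row["fraction"],
                    polymerase=row["polymerase"],
                    condition=row["condition"],
                    replicate=int(row["replicate"]),
                    fastq_path=row["fastq_path"],
                )
            )
    validate_sample_sheet(entries)
    return entries


def validate_sample_sheet(entries: Sequence[SampleSheetEntry]) -> None:
    ids = [e.library_id for e in entries]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate library ids: {dupes}")
    inputs = {
        (e.polymerase, e.condition, e.replicate) for e in entries if e.fraction == "input"
    }
    for e in entries:
        if e.fraction == "IP":
            key = (e.polymerase, e.condition, e.replicate)
            if key not in inputs:
                raise ValueError(
                    f"IP library {e.library_id} has no matching input library "
                    f"for (polymerase={key[0]}, condition={key[1]}, replicate={key[2]})"
                )


def write_sample_sheet(entries: Sequence[SampleSheetEntry], path: str | Path) -> None:
    with open(path, "w") as out:
        out.write("\t".join(SAMPLE_SHEET_COLUMNS) + "\n")
        for e in entries:
            out.write(
                f"{e.library_id}\t{e.fraction}\t{e.polymerase}\t{e.condition}\t"
                f"{e.replicate}\t{e.fastq_path}\n"
            )
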