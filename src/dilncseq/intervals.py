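"""Genomic coordinate primitives.

Every coordinate in this package is 0-based, half-open ``[start, end)`` on a
named chromosome, with strand restricted to ``+``/``-``.  File formats that use
other conventions (GFF3 is 1-based inclusive) are converted at the I/O
boundary and nowhere else.
"""

from __future__ import annotations

from dataclasses import dataclass, field

STRANDS = ("+", "-")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved, N self-paired)."""
    return seq.translate(_COMPLEMENT)[::-1]


def opposite_strand(strand: str) -> str:
    return "-" if strand == "+" else "+"


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval", flank: int = 0) -> bool:
        """True if the intervals share >= 1 nt after widening self by ``flank``."""
        if self.chrom != other.chrom:
            return False
        return other.start < self.end + flank and other.end > self.start - flank


@dataclass(frozen=True)
class GeneModel:
    """A gene's span and exon/intron structure.

    Exons are stored sorted by genomic start regardless of transcription
    order; introns are the gaps between consecutive exons.  A gene "has an
    intron" exactly when it carries two or more exons — the property that
    modulates break-induced antisense transcription in the simulator.
    """

    gene_id: str
    span: GenomicInterval
    exons: tuple[GenomicInterval, ...] = field(default=())

    def __post_init__(self) -> None:
        exons = tuple(sorted(self.exons, key=lambda e: e.start))
        object.__setattr__(self, "exons", exons)
        prev_end = None
        for exon in exons:
            if exon.chrom != self.span.chrom or exon.strand != self.span.strand:
                raise ValueError(
                    f"gene {self.gene_id}: exon {exon} not on the gene's "
                    "chromosome/strand"
                )
            if exon.start < self.span.start or exon.end > self.span.end:
                raise ValueError(
                    f"gene {self.gene_id}: exon {exon.start}-{exon.end} outside "
                    f"gene span {self.span.start}-{self.span.end}"
                )
            if prev_end is not None and exon.start < prev_end:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")
            prev_end = exon.end

    @property
    def chrom(self) -> str:
        return self.span.chrom

    @property
    def strand(self) -> str:
        return self.span.strand

    @property
    def introns(self) -> tuple[GenomicInterval, ...]:
        gaps = []
        for left, right in zip(self.exons, self.exons[1:]):
            if right.start > left.end:
                gaps.append(
                    GenomicInterval(self.chrom, left.end, right.start, self.strand)
                )
        return tuple(gaps)

    @property
    def has_intron(self) -> bool:
        return len(self.exons) >= 2

    @property
    def tss(self) -> int:
        """0-based position of the transcription start site."""
        return self.span.start if self.strand == "+" else self.span.end - 1
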