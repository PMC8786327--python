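"""Locus-level strand-resolved counting and the two normalised statistics.

For a locus, a read is *sense* when its alignment strand equals the gene
strand and *antisense* otherwise.  Two normalisations are supported:

* antisense fraction ``antisense / (sense + antisense)`` — antisense reads
  relative to the total transcriptional activity of the locus in that
  library;
* antisense ppm ``1e6 * antisense / total_genome_matching`` — antisense
  reads per million genome-matching reads in the library.

A locus with no reads at all has an *undefined* fraction: the statistic is
flagged (``None``), never silently reported as zero, so low-coverage loci
are visible rather than averaged away.  Recovery ratios (IP ppm over input
ppm for a transcript class) quantify polymerase specificity of the
immunoprecipitation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .align import Alignment
from .intervals import GeneModel, GenomicInterval
from .io_formats import SampleSheetEntry

PPM = 1_000_000


@dataclass(frozen=True)
class LocusStrandCounts:
    """Sense/antisense read counts at one locus in one library."""

    locus_id: str
    library_id: str
    sense: int
    antisense: int
    total_genome_matching: int

    def __post_init__(self) -> None:
        if self.sense < 0 or self.antisense < 0:
            raise ValueError("counts must be non-negative")
        if self.sense + self.antisense > self.total_genome_matching:
            raise ValueError(
                f"{self.locus_id}/{self.library_id}: locus reads exceed the "
                "library's genome-matching total"
            )


def count_locus(
    alignments: Iterable[Alignment],
    gene: GeneModel,
    total_genome_matching: int,
    library_id: str = "",
    flank: int = 0,
) -> LocusStrandCounts:
    """Count sense/antisense reads overlapping the gene span (>= 1 nt).

    The locus extent is ``[span.start - flank, span.end + flank)``; each read
    is counted at most once per locus.
    """
    if flank < 0:
        raise ValueError(f"flank must be >= 0, got {flank}")
    lo = gene.span.start - flank
    hi = gene.span.end + flank
    sense = antisense = 0
    for aln in alignments:
        iv = aln.interval
        if iv.chrom == gene.chrom and iv.start < hi and iv.end > lo:
            if iv.strand == gene.strand:
                sense += 1
            else:
                antisense += 1
    return LocusStrandCounts(
        gene.gene_id, library_id, sense, antisense, total_genome_matching
    )


def antisense_fraction(counts: LocusStrandCounts) -> float | None:
    """``antisense / (sense + antisense)``; ``None`` when the locus has no reads."""
    total = counts.sense + counts.antisense
    if total == 0:
        return None
    return counts.antisense / total


def antisense_ppm(counts: LocusStrandCounts) -> float:
    """Antisense reads per million genome-matching reads in the library."""
    if counts.total_genome_matching <= 0:
        raise ValueError(
            f"{counts.locus_id}/{counts.library_id}: total_genome_matching must "
            "be > 0 for ppm normalisation"
        )
    return PPM * counts.antisense / counts.total_genome_matching


@dataclass(frozen=True)
class RecoveryRatio:
    """IP/input ppm ratio for a transcript class; ``None`` when undefined."""

    class_id: str
    ip_ppm: float
    input_ppm: float

    @property
    def recovery(self) -> float | None:
        if self.input_ppm == 0:
            return None
        return self.ip_ppm / self.input_ppm


def _class_tree(intervals: Sequence[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    return trees


def count_class(
    alignments: Iterable[Alignment], intervals: Sequence[GenomicInterval]
) -> int:
    """Reads overlapping any interval of a class (strand-blind, once per read)."""
    trees = _class_tree(intervals)
    n = 0
    for aln in alignments:
        tree = trees.get(aln.interval.chrom)
        if tree is not None and tree.overlaps(aln.interval.start, aln.interval.end):
            n += 1
    return n


def recovery(
    class_id: str,
    class_intervals: Sequence[GenomicInterval],
    ip_alignments: Iterable[Alignment],
    ip_total: int,
    input_alignments: Iterable[Alignment],
    input_total: int,
) -> RecoveryRatio:
    """IP-versus-input recovery for a transcript class.

    Both libraries are normalised to reads per million genome-matching reads
    before the ratio; zero input signal flags the ratio undefined.
    """
    if not class_intervals:
        raise ValueError(f"class {class_id!r}: empty interval collection")
    if ip_total <= 0 or input_total <= 0:
        raise ValueError(f"class {class_id!r}: both library totals must be > 0")
    ip_ppm = PPM * count_class(ip_alignments, class_intervals) / ip_total
    input_ppm = PPM * count_class(input_alignments, class_intervals) / input_total
    return RecoveryRatio(class_id, ip_ppm, input_ppm)


def cut_vs_uncut_table(
    counts: Iterable[LocusStrandCounts],
    design: Mapping[str, SampleSheetEntry] | Sequence[SampleSheetEntry],
) -> pd.DataFrame:
    """Materialise the reciprocal-control design as a tidy replicate table.

    Each row is one (locus, library): libraries in which this locus was the
    cleavage target are labelled ``cut``; libraries in which the *other*
    locus was cleaved serve as that locus's ``uncut`` control.  Columns carry
    both statistics (fraction may be NA when the locus had no reads).
    Raises if any (polymerase, fraction, condition) cell lacks a replicate
    present in the others.
    """
    if not isinstance(design, Mapping):
        design = {e.library_id: e for e in design}
    rows = []
    for c in counts:
        entry = design[c.library_id]
        frac = antisense_fraction(c)
        rows.append(
            {
                "locus_id": c.locus_id,
                "library_id": c.library_id,
                "condition": "cut" if entry.condition == c.locus_id else "uncut",
                "cleaved_locus": entry.condition,
                "replicate": entry.replicate,
                "fraction": entry.fraction,
                "polymerase": entry.polymerase,
                "sense": c.sense,
                "antisense": c.antisense,
                "total_genome_matching": c.total_genome_matching,
                "antisense_fraction": float("nan") if frac is None else frac,
                "antisense_ppm": antisense_ppm(c),
            }
        )
    table = pd.DataFrame(rows).sort_values(
        ["locus_id", "polymerase", "fraction", "condition", "replicate"],
        kind="mergesort",
    )
    # replicate pairing must be complete within each design cell
    for (locus, pol, fraction), cell in table.groupby(
        ["locus_id", "polymerase", "fraction"]
    ):
        reps = {
            cond: set(sub["replicate"]) for cond, sub in cell.groupby("condition")
        }
        expected = set.union(*reps.values())
        for cond, have in reps.items():
            if have != expected:
                raise ValueError(
                    f"incomplete replicate pairing for locus={locus}, "
                    f"polymerase={pol}, fraction={fraction}, condition={cond}: "
                    f"have replicates {sorted(have)}, expected {sorted(expected)}"
                )
    return table.reset_index(drop=True)
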