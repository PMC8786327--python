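"""RNA polymerase III terminator signals and read-density comparison.

Pol-III terminates on a run of uridines in the nascent transcript.  For a
transcript read 5'→3' on the ``+`` genome strand this is a genomic T-run;
for a ``-``-strand transcript (e.g. a break-induced antisense RNA inside a
``+`` gene) it is a genomic A-run.  ``find_terminators`` reports maximal
homopolymer runs of at least ``min_run`` nt (default 8, the canonical
strong-terminator length).

If pol-III transcribed such an antisense RNA, small-RNA read density should
drop downstream (in transcription direction) of the terminator;
``density_across_terminator`` quantifies this with strand-filtered reads per
nucleotide on each side, excluding a short window around the homopolymer
where library construction drops out for technical reasons, and attaches an
exact binomial p-value for equal density.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping

from .align import Alignment
from .intervals import GeneModel, GenomicInterval, revcomp
from .stats import binomial_density_test

DEFAULT_MIN_RUN = 8  # nt of U in the transcript: terminates most pol-III complexes
DEFAULT_EXCLUSION = 20  # nt total window around the run with technical read dropout


@dataclass(frozen=True)
class Hairpin:
    stem_length: int
    loop_length: int
    offset: int  # nt between hairpin 3' end and the run, in transcript direction


@dataclass(frozen=True)
class TerminatorSite:
    """A candidate pol-III termination signal for a stated orientation."""

    position: GenomicInterval  # the homopolymer, genome coordinates
    transcription_strand: str
    run_length: int
    hairpin: Hairpin | None = None

    def __post_init__(self) -> None:
        if self.run_length != self.position.length:
            raise ValueError("run_length must equal the homopolymer interval length")


def _sequence(genome: Mapping[str, str] | str, chrom: str) -> str:
    if isinstance(genome, str):
        return genome
    return genome[chrom]


def find_terminators(
    genome: Mapping[str, str] | str,
    region: GenomicInterval,
    transcription_strand: str,
    min_run: int = DEFAULT_MIN_RUN,
) -> list[TerminatorSite]:
    """Maximal homopolymer runs that read as poly-U on the given transcript.

    A ``+`` transcript terminates on genomic T-runs; a ``-`` transcript on
    genomic A-runs (which read as U once transcribed).  Runs are maximal —
    nested sub-runs are never reported — and must lie entirely within
    ``region``.
    """
    seq = _sequence(genome, region.chrom)
    if region.end > len(seq):
        raise ValueError(f"region {region} extends beyond the chromosome")
    base = "T" if transcription_strand == "+" else "A"
    window = seq[region.start : region.end].upper()
    sites = []
    for match in re.finditer(f"{base}{{{min_run},}}", window):
        start = region.start + match.start()
        end = region.start + match.end()
        # maximality within the full chromosome, not just the window
        if start > 0 and seq[start - 1].upper() == base:
            continue
        if end < len(seq) and seq[end].upper() == base:
            continue
        sites.append(
            TerminatorSite(
                GenomicInterval(region.chrom, start, end, transcription_strand),
                transcription_strand,
                end - start,
            )
        )
    return sites


def find_hairpin(
    genome: Mapping[str, str] | str,
    site: TerminatorSite,
    window: int = 60,
    min_stem: int = 5,
    max_loop: int = 10,
    allow_gu: bool = False,
) -> Hairpin | None:
    """Best inverted repeat in the window upstream of the run (transcript sense).

    "Upstream" means 5' of the poly-U in the transcript: genomically left of
    a T-run for a ``+`` transcript, right of an A-run for a ``-`` transcript.
    The stem pairs Watson-Crick (G·U wobble optional); ties broken by longest
    stem, then smallest offset from the run.  Not a free-energy fold — just
    the structural element a terminator scan looks for.
    """
    seq = _sequence(genome, site.position.chrom)
    if site.transcription_strand == "+":
        lo = max(0, site.position.start - window)
        upstream = seq[lo : site.position.start].upper()
        transcript = upstream  # already 5'->3'
    else:
        hi = min(len(seq), site.position.end + window)
        upstream = seq[site.position.end : hi].upper()
        transcript = revcomp(upstream)  # transcript runs right-to-left
    # transcript[i] is upstream sequence 5'->3'; offset measured from its 3' end
    n = len(transcript)
    pairs = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
    if allow_gu:
        # wobble in RNA: G pairs U (genomic T)
        pairs |= {("G", "T"), ("T", "G")}
    best: Hairpin | None = None
    for i in range(n):
        for j in range(n - 1, i, -1):
            # extend a stem pairing transcript[i+s] with transcript[j-s]
            stem = 0
            while (
                i + stem < j - stem
                and (transcript[i + stem], transcript[j - stem]) in pairs
            ):
                stem += 1
            # a self-complementary loop lets the extension swallow the loop;
            # back off to the longest stem leaving a legal loop
            loop = (j - stem) - (i + stem) + 1
            while stem >= min_stem and (loop < 1 or loop > max_loop):
                stem -= 1
                loop = (j - stem) - (i + stem) + 1
            if stem < min_stem or loop < 1 or loop > max_loop:
                continue
            offset = n - 1 - j
            cand = Hairpin(stem_length=stem, loop_length=loop, offset=offset)
            if (
                best is None
                or cand.stem_length > best.stem_length
                or (cand.stem_length == best.stem_length and cand.offset < best.offset)
            ):
                best = cand
    return best


@dataclass(frozen=True)
class DensityComparison:
    """Read density up/downstream of a terminator, in transcription direction."""

    upstream_density: float
    downstream_density: float
    upstream_count: int
    downstream_count: int
    upstream_length: int
    downstream_length: int
    excluded: GenomicInterval
    ratio: float | None  # upstream/downstream; None when undefined
    p: float | None  # exact binomial test of equal per-nt density


def density_across_terminator(
    alignments: Iterable[Alignment],
    gene: GeneModel,
    site: TerminatorSite,
    exclusion: int = DEFAULT_EXCLUSION,
    strand_filter: str | None = None,
) -> DensityComparison:
    """Compare strand-filtered read density before and after a terminator.

    Segments run from the gene span edges to an exclusion window of
    ``exclusion`` nt total centred on the homopolymer (always covering it);
    "upstream" is the 5' side in transcription direction.  Reads touching the
    exclusion window are discarded; remaining reads count toward any segment
    they overlap by >= 1 nt.  Attaches the upstream/downstream density ratio
    and an exact binomial p-value; both are flagged undefined (``None``)
    when no reads survive.
    """
    span = gene.span
    pos = site.position
    if pos.start < span.start or pos.end > span.end:
        raise ValueError("terminator site must lie inside the gene span")
    centre = (pos.start + pos.end) / 2
    half = exclusion / 2
    ex_start = max(0, min(pos.start, int(centre - half)))
    ex_end = max(pos.end, int(centre + half))
    excluded = GenomicInterval(pos.chrom, ex_start, ex_end, site.transcription_strand)

    left = (span.start, ex_start)  # genomic left segment
    right = (ex_end, span.end)  # genomic right segment
    if left[1] - left[0] <= 0 or right[1] - right[0] <= 0:
        raise ValueError("exclusion window leaves a zero-length segment")
    if site.transcription_strand == "+":
        up, down = left, right
    else:
        up, down = right, left

    up_count = down_count = 0
    for aln in alignments:
        iv = aln.interval
        if iv.chrom != span.chrom:
            continue
        if strand_filter is not None and iv.strand != strand_filter:
            continue
        if iv.start < ex_end and iv.end > ex_start:
            continue  # technical-dropout window
        if iv.start < up[1] and iv.end > up[0]:
            up_count += 1
        if iv.start < down[1] and iv.end > down[0]:
            down_count += 1

    up_len = up[1] - up[0]
    down_len = down[1] - down[0]
    up_density = up_count / up_len
    down_density = down_count / down_len
    if up_count + down_count == 0:
        ratio = p = None
    else:
        ratio = up_density / down_density if down_density > 0 else float("inf")
        p = binomial_density_test(up_count, up_len, down_count, down_len)
    return DensityComparison(
        upstream_density=up_density,
        downstream_density=down_density,
        upstream_count=up_count,
        downstream_count=down_count,
        upstream_length=up_len,
        downstream_length=down_len,
        excluded=excluded,
        ratio=ratio,
        p=p,
    )
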