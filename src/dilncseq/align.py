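"""Exact-match, strand-aware short-read placement.

The mapping policy is the one used for polymerase-footprint libraries: no
mismatches are tolerated, every perfect full-length hit on either strand is
enumerated, and a read with several perfect hits is reported exactly once at
a uniformly random one of them (under an explicit, mandatory seed).  Reads
containing N never map.

The index is a plain k-mer hash over the forward genome; candidate seeds are
verified by full-string comparison, so no seed-only false positives are
possible.  This is adequate for the short (20-28 nt) benzonase footprints the
protocol produces; it makes no attempt at mismatch, indel or spliced
alignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from .intervals import GenomicInterval, revcomp
from .io_formats import read_fastq

logger = logging.getLogger(__name__)

DEFAULT_K = 12
SIZE_MIN = 20  # nt, lower bound of the PAGE size selection
SIZE_MAX = 28  # nt, upper bound


@dataclass
class ExactIndex:
    """k-mer lookup over the forward strand of a genome."""

    k: int
    lookup: dict[str, list[tuple[str, int]]] = field(default_factory=dict)

    @property
    def n_entries(self) -> int:
        return sum(len(v) for v in self.lookup.values())


@dataclass(frozen=True)
class Alignment:
    """A read's unique placement after the mapping policy.

    ``strand`` is the genome strand the read matches forward; a read is
    antisense to a gene when this differs from the gene's strand.
    ``n_candidates`` records how many perfect hits existed before the random
    single-report assignment.
    """

    read_id: str
    interval: GenomicInterval
    n_candidates: int

    def __post_init__(self) -> None:
        if self.n_candidates < 1:
            raise ValueError("an alignment must come from >= 1 candidate hit")

    @property
    def strand(self) -> str:
        return self.interval.strand


@dataclass
class SizeSelectStats:
    total: int = 0
    kept: int = 0

    @property
    def dropped(self) -> int:
        return self.total - self.kept


def size_select(
    reads: Iterable[tuple[str, str, str]],
    min_len: int = SIZE_MIN,
    max_len: int = SIZE_MAX,
    stats: SizeSelectStats | None = None,
) -> Iterator[tuple[str, str, str]]:
    """Keep reads whose length lies in ``[min_len, max_len]`` (inclusive).

    Mirrors the PAGE purification of 20-28 nt fragments.  Retention counts
    accumulate in ``stats`` (if given) and are logged at the end.
    """
    stats = stats if stats is not None else SizeSelectStats()
    for record in reads:
        stats.total += 1
        if min_len <= len(record[1]) <= max_len:
            stats.kept += 1
            yield record
    logger.info(
        "size_select: kept %d/%d reads (%d outside [%d,%d] nt)",
        stats.kept, stats.total, stats.dropped, min_len, max_len,
    )


def build_index(genome: Mapping[str, str], k: int = DEFAULT_K) -> ExactIndex:
    """Index every N-free k-mer of the forward genome."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    lookup: dict[str, list[tuple[str, int]]] = {}
    for chrom, seq in genome.items():
        seq = seq.upper()
        for pos in range(len(seq) - k + 1):
            kmer = seq[pos : pos + k]
            if "N" in kmer:
                continue
            lookup.setdefault(kmer, []).append((chrom, pos))
    for hits in lookup.values():
        hits.sort()
    return ExactIndex(k=k, lookup=lookup)


def find_all_hits(
    read: str, index: ExactIndex, genome: Mapping[str, str]
) -> list[GenomicInterval]:
    """Exhaustive perfect full-length matches of ``read`` on both strands.

    Seed-and-extend from the k-mer index with full-string verification.
    Reads containing N (or shorter than k) return no hits.
    """
    read = read.upper()
    n = len(read)
    if n < index.k or "N" in read:
        return []
    hits: list[GenomicInterval] = []
    # forward: read matches the '+' strand verbatim
    for chrom, pos in index.lookup.get(read[: index.k], ()):
        if genome[chrom][pos : pos + n] == read:
            hits.append(GenomicInterval(chrom, pos, pos + n, "+"))
    # reverse: the read's reverse complement matches the '+' strand
    rc = revcomp(read)
    for chrom, pos in index.lookup.get(rc[: index.k], ()):
        if genome[chrom][pos : pos + n] == rc:
            hits.append(GenomicInterval(chrom, pos, pos + n, "-"))
    return hits


def assign_unique(
    read_id: str, hits: Sequence[GenomicInterval], rng: np.random.Generator
) -> Alignment | None:
    """Report a read once: its sole hit, or a uniformly random one of several."""
    if not hits:
        return None
    if len(hits) == 1:
        return Alignment(read_id, hits[0], 1)
    choice = hits[int(rng.integers(len(hits)))]
    return Alignment(read_id, choice, len(hits))


@dataclass
class MappingSummary:
    library_id: str = ""
    input_reads: int = 0
    mapped: int = 0

    @property
    def unmapped(self) -> int:
        return self.input_reads - self.mapped

    @property
    def total_genome_matching(self) -> int:
        return self.mapped


def align_library(
    reads: Iterable[tuple[str, str, str]] | str | Path,
    index: ExactIndex,
    genome: Mapping[str, str],
    seed: int | np.random.Generator,
    library_id: str = "",
) -> tuple[list[Alignment], MappingSummary]:
    """Map a library; returns alignments and the genome-matching total.

    ``total_genome_matching`` (the ppm normaliser) is simply the number of
    mapped reads.  Deterministic under ``seed``; multi-mapper assignment
    consumes the rng in read order.
    """
    if isinstance(reads, (str, Path)):
        reads = read_fastq(reads)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    summary = MappingSummary(library_id=library_id)
    alignments: list[Alignment] = []
    for read_id, seq, _qual in reads:
        summary.input_reads += 1
        aln = assign_unique(read_id, find_all_hits(seq, index, genome), rng)
        if aln is not None:
            summary.mapped += 1
            alignments.append(aln)
    logger.info(
        "align_library[%s]: %d/%d reads mapped",
        library_id, summary.mapped, summary.input_reads,
    )
    return alignments, summary


def naive_all_hits(read: str, genome: Mapping[str, str]) -> list[GenomicInterval]:
    """Brute-force all-positions scan; the oracle the index must agree with."""
    read = read.upper()
    n = len(read)
    if n == 0 or "N" in read:
        return []
    hits = []
    rc = revcomp(read)
    for chrom, seq in genome.items():
        for query, strand in ((read, "+"), (rc, "-")):
            pos = seq.find(query)
            while pos != -1:
                hits.append(GenomicInterval(chrom, pos, pos + n, strand))
                pos = seq.find(query, pos + 1)
    return hits
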