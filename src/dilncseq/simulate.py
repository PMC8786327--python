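"""Generative model of a polymerase-specific nascent-RNA (NET-seq) experiment.

The simulator produces FASTA/GFF3/FASTQ fixtures with the statistical
structure of a break-induction experiment in cultured cells:

* chromatin-associated nascent reads with promoter-proximal pausing
  (mixture of a truncated normal near the TSS and a uniform gene body);
* nuclease-protected polymerase footprints of 23-26 nt — each read is the
  3'-terminal stump of a nascent transcript ending at the active site;
* cytoplasmic contamination (a fixed 23-nt miRNA and rRNA-derived
  fragments) plus mature spliced-mRNA fragments restricted to exons;
* polymerase-specific immunoprecipitation modelled as per-read Bernoulli
  thinning of the chromatin input pool: a footprint survives IP with
  probability ``ip_capture`` when its polymerase carries the epitope tag and
  ``ip_background`` otherwise — so the IP read multiset is a subset of the
  input pool and every recovery ratio has a closed-form expectation;
* break-induced antisense transcription (dilncRNA): antisense polymerase
  positions uniform between the TSS and the cut site, with Poisson mean
  ``base_antisense`` at an uncut locus, multiplied upon cutting by
  ``induction_factor`` and — only if the cut gene has an intron — by
  ``spliceosome_boost``.

All randomness flows from one root seed through named sub-streams, so the
whole experiment (and every library within it) is reproducible byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GeneModel, GenomicInterval, opposite_strand, revcomp
from .io_formats import (
    SampleSheetEntry,
    write_bed,
    write_fasta,
    write_fastq,
    write_gff3,
    write_sample_sheet,
)

POLYMERASES = ("polII", "polIII")
UNTAGGED = "none"  # contamination / background reads carry no polymerase


def substream(seed: int, name: str) -> np.random.Generator:
    """Named child rng of a root seed (stable across runs and platforms)."""
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])


@dataclass(frozen=True)
class GeneSpec:
    """Planted gene: position, structure and expected nascent reads/library."""

    gene_id: str
    start: int
    length: int
    strand: str
    n_exons: int
    expression: float  # expected nascent polymerase footprints per library
    polymerase: str = "polII"


@dataclass(frozen=True)
class ContaminationSpec:
    mirna_seq: str = "TGAGATCATTTTGAAAGCTGATT"  # fixed 23-nt cytoplasmic miRNA
    mirna_copies: float = 800.0
    rrna_start: int = 27000
    rrna_length: int = 1500
    rrna_copies: float = 1500.0


def _default_genes() -> tuple[GeneSpec, ...]:
    return (
        # intron-containing cleavage target (3 exons -> 2 introns)
        GeneSpec("geneA", 2000, 4000, "+", 3, 2000.0),
        # intronless reciprocal target
        GeneSpec("geneB", 9000, 2500, "-", 1, 2000.0),
        # neighbouring control locus
        GeneSpec("geneC", 14000, 2000, "+", 2, 1500.0),
        # highly expressed distal control (actin-like)
        GeneSpec("geneD", 19000, 3000, "+", 2, 4000.0),
        # pol-III transcribed tRNA-like locus
        GeneSpec("trnaA", 25000, 300, "+", 1, 1500.0, polymerase="polIII"),
    )


@dataclass
class SimulationConfig:
    """All generative parameters of the synthetic experiment."""

    seed: int = 0
    chrom: str = "toy1"
    genome_length: int = 30000
    genes: tuple[GeneSpec, ...] = field(default_factory=_default_genes)
    # promoter-proximal pausing: weight, offset from TSS and spread (nt)
    pause_weight: float = 0.5
    pause_offset: int = 40
    pause_sd: float = 15.0
    # nuclease-protected footprint length law on {23..26} nt
    footprint_lengths: dict[int, float] = field(
        default_factory=lambda: {23: 0.25, 24: 0.25, 25: 0.25, 26: 0.25}
    )
    size_selection: tuple[int, int] = (20, 28)
    # cleavage design: offsets (nt from TSS) of the plantable cut per gene
    cut_targets: dict[str, int] = field(
        default_factory=lambda: {"geneA": 3300, "geneB": 1800}
    )
    cut: tuple[str, int] | None = None  # active cut for single-condition runs
    # break-induced antisense transcription: the baseline is kept far below
    # sense transcription so that an untagged-polymerase IP leaves the locus
    # signal noise-dominated (the antisense fraction itself is invariant
    # under uniform thinning)
    base_antisense: float = 2.0  # expected antisense polymerases, uncut locus
    induction_factor: float = 5.0  # fold induction upon cutting
    spliceosome_boost: float = 2.0  # extra fold, intron-containing genes only
    # contamination and background
    contamination: ContaminationSpec = field(default_factory=ContaminationSpec)
    mrna_contamination_rate: float = 0.3  # spliced-mRNA fragments per unit expression
    background_rate: float = 300.0  # uniform chromatin background reads
    # immunoprecipitation thinning probabilities
    ip_capture: float = 0.8  # tagged polymerase
    ip_background: float = 0.005  # everything else (non-specific carry-over)
    library_depth: float | None = None  # expected total reads; None = natural sum
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if not (0 <= self.ip_background < self.ip_capture <= 1):
            raise ValueError("need 0 <= ip_background < ip_capture <= 1")
        if not 0 <= self.pause_weight <= 1:
            raise ValueError("pause_weight must be in [0,1]")
        if self.induction_factor < 1 or self.spliceosome_boost < 1:
            raise ValueError("induction factors must be >= 1")
        for rate in (self.base_antisense, self.background_rate,
                     self.mrna_contamination_rate):
            if rate < 0:
                raise ValueError("rates must be >= 0")
        law = self.footprint_lengths
        if abs(sum(law.values()) - 1.0) > 1e-9 or any(p < 0 for p in law.values()):
            raise ValueError("footprint_lengths must be a probability law")
        if any(not 23 <= length <= 26 for length in law):
            raise ValueError("footprint lengths must lie in [23,26] nt")
        ordered = sorted(self.genes, key=lambda g: g.start)
        prev_end = 0
        for g in ordered:
            if g.start < prev_end:
                raise ValueError(f"gene {g.gene_id} overlaps the previous gene")
            if g.start + g.length > self.genome_length:
                raise ValueError(f"gene {g.gene_id} extends beyond the genome")
            prev_end = g.start + g.length
        for gene_id, offset in self.cut_targets.items():
            spec = self.gene_spec(gene_id)
            if not 0 < offset < spec.length:
                raise ValueError(
                    f"cut offset {offset} outside gene {gene_id} (len {spec.length})"
                )

    def gene_spec(self, gene_id: str) -> GeneSpec:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(f"unknown gene {gene_id!r}")

    @property
    def rate_scale(self) -> float:
        """Factor scaling every rate so expected depth hits library_depth."""
        if self.library_depth is None:
            return 1.0
        c = self.contamination
        natural = (
            sum(g.expression for g in self.genes)
            + self.base_antisense * sum(1 for g in self.genes if g.polymerase == "polII")
            + self.mrna_contamination_rate
            * sum(g.expression for g in self.genes if g.polymerase == "polII")
            + c.mirna_copies
            + c.rrna_copies
            + self.background_rate
        )
        return self.library_depth / natural

    def cut_site(self, gene: GeneModel) -> int:
        """Genomic coordinate of the (possibly hypothetical) cut in ``gene``.

        Registered targets use their configured TSS offset; other genes use
        the span midpoint as the hypothetical break position for baseline
        antisense sampling.
        """
        offset = self.cut_targets.get(gene.gene_id)
        if offset is None:
            return (gene.span.start + gene.span.end) // 2
        if gene.strand == "+":
            return gene.span.start + offset
        return gene.span.end - 1 - offset


@dataclass(frozen=True)
class PolymerasePosition:
    """Latent state: one engaged polymerase's active site."""

    polymerase: str
    chrom: str
    position: int
    transcription_strand: str
    origin: str  # sense | dilncRNA | contamination | background


@dataclass(frozen=True)
class Footprint:
    """A protected RNA stump ready to become a sequencing read."""

    interval: GenomicInterval
    sequence: str
    origin: str
    polymerase: str


@dataclass
class ToyGenome:
    genome: dict[str, str]
    genes: list[GeneModel]
    classes: dict[str, list[GenomicInterval]]
    mirna_interval: GenomicInterval
    rrna_interval: GenomicInterval

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(f"unknown gene {gene_id!r}")


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_sequence(n: int, rng: np.random.Generator) -> np.ndarray:
    return _BASES[rng.integers(0, 4, n)]


def _break_homopolymers(seq: np.ndarray, max_run: int = 5) -> None:
    """Interrupt A/T runs longer than ``max_run`` so no accidental pol-III
    terminator survives outside the planted one."""
    for base in (ord("A"), ord("T")):
        run = 0
        for i in range(len(seq)):
            if seq[i] == base:
                run += 1
                if run > max_run:
                    seq[i] = ord("C")
                    run = 0
            else:
                run = 0


def _make_exons(spec: GeneSpec) -> list[GenomicInterval]:
    """Deterministic alternating exon/intron layout: 2k-1 equal blocks."""
    k = spec.n_exons
    blocks = 2 * k - 1
    size = spec.length // blocks
    exons = []
    for i in range(k):
        lo = spec.start + 2 * i * size
        hi = spec.start + spec.length if i == k - 1 else lo + size
        exons.append((lo, hi))
    return exons


def build_toy_genome(config: SimulationConfig) -> ToyGenome:
    """Plant the configured genes in a random genome (deterministic per seed).

    The cleavage-target gene carries a serendipitous run of eight adenosines
    on its sense strand inside its second intron — a pol-III terminator for
    the antisense transcript — preceded (in antisense transcript direction)
    by a planted 6-bp stem / 4-nt loop inverted repeat.  All other A/T runs
    >= 6 nt are broken so the planted terminator is the only one.  The fixed
    contaminating miRNA sequence is planted so it genome-matches.
    """
    rng = substream(config.seed, "genome")
    seq = _random_sequence(config.genome_length, rng)
    _break_homopolymers(seq)

    genes: list[GeneModel] = []
    for spec in config.genes:
        exons = tuple(
            GenomicInterval(config.chrom, lo, hi, spec.strand)
            for lo, hi in _make_exons(spec)
        )
        span = GenomicInterval(
            config.chrom, spec.start, spec.start + spec.length, spec.strand
        )
        genes.append(GeneModel(spec.gene_id, span, exons))

    toy = ToyGenome(
        genome={},
        genes=genes,
        classes={},
        mirna_interval=GenomicInterval(
            config.chrom,
            config.genome_length - 200,
            config.genome_length - 200 + len(config.contamination.mirna_seq),
            "+",
        ),
        rrna_interval=GenomicInterval(
            config.chrom,
            config.contamination.rrna_start,
            config.contamination.rrna_start + config.contamination.rrna_length,
            "+",
        ),
    )

    # plant the A8 terminator + upstream hairpin in the cut gene's 2nd intron
    for gene_id in config.cut_targets:
        gene = next(g for g in genes if g.gene_id == gene_id)
        if len(gene.introns) >= 2 and gene.strand == "+":
            intron = gene.introns[1]
            mid = (intron.start + intron.end) // 2
            seq[mid : mid + 8] = ord("A")
            # hairpin element 5' of the T8 in the antisense transcript, i.e.
            # genomically right of the A-run: stem6 + loop4 + revcomp(stem6)
            stem = "GCTGCG"
            element = stem + "CTTC" + revcomp(stem)
            pos = mid + 8 + 7  # 7-nt offset between hairpin and run
            seq[pos : pos + len(element)] = np.frombuffer(
                element.encode(), dtype=np.uint8
            )

    mirna = config.contamination.mirna_seq.upper()
    mi = toy.mirna_interval
    seq[mi.start : mi.end] = np.frombuffer(mirna.encode(), dtype=np.uint8)

    toy.genome = {config.chrom: seq.tobytes().decode()}
    toy.classes = {
        "cds": [e for g in genes if _is_polii(config, g) for e in g.exons],
        "intron": [i for g in genes if _is_polii(config, g) for i in g.introns],
        "trna": [g.span for g in genes if not _is_polii(config, g)],
    }
    return toy


def _is_polii(config: SimulationConfig, gene: GeneModel) -> bool:
    return config.gene_spec(gene.gene_id).polymerase == "polII"


# ---------------------------------------------------------------------------
# latent-position sampling


def sample_sense_positions(
    gene: GeneModel,
    lam: float,
    rng: np.random.Generator,
    pause_weight: float = 0.5,
    pause_offset: int = 40,
    pause_sd: float = 15.0,
    polymerase: str = "polII",
) -> list[PolymerasePosition]:
    """Poisson(lam) nascent polymerases along the gene, with pausing.

    Positions follow the mixture ``pause_weight * Normal(TSS + offset, sd)``
    (truncated to the gene span) + ``(1 - pause_weight) * Uniform(span)``.
    """
    n = int(rng.poisson(lam))
    if n == 0:
        return []
    lo, hi = gene.span.start, gene.span.end
    paused = rng.random(n) < pause_weight
    pos = rng.integers(lo, hi, n)
    n_paused = int(paused.sum())
    if n_paused:
        centre = lo + pause_offset if gene.strand == "+" else hi - 1 - pause_offset
        draws = np.rint(rng.normal(centre, pause_sd, n_paused)).astype(np.int64)
        bad = (draws < lo) | (draws >= hi)
        while bad.any():  # truncation by rejection
            draws[bad] = np.rint(
                rng.normal(centre, pause_sd, int(bad.sum()))
            ).astype(np.int64)
            bad = (draws < lo) | (draws >= hi)
        pos[paused] = draws
    return [
        PolymerasePosition(polymerase, gene.chrom, int(p), gene.strand, "sense")
        for p in pos
    ]


def dilncrna_rate(
    lam0: float, f_cut: float, f_intron: float, is_cut: bool, has_intron: bool
) -> float:
    """Expected antisense polymerases at a locus under the induction model."""
    if not is_cut:
        return lam0
    return lam0 * f_cut * (f_intron if has_intron else 1.0)


def sample_dilncrna_positions(
    gene: GeneModel,
    cut_site: int,
    lam0: float,
    f_cut: float,
    f_intron: float,
    is_cut: bool,
    rng: np.random.Generator,
    polymerase: str = "polII",
) -> list[PolymerasePosition]:
    """Break-induced antisense polymerases, uniform between TSS and cut site.

    The Poisson mean is ``lam0`` at an uncut locus and
    ``lam0 * f_cut * f_intron`` (the intron boost applying only to
    intron-containing genes) upon cutting.  Transcription runs opposite to
    the gene, from the break back toward the TSS.
    """
    if not (gene.span.start <= cut_site < gene.span.end):
        raise ValueError(f"cut site {cut_site} outside gene {gene.gene_id}")
    lam = dilncrna_rate(lam0, f_cut, f_intron, is_cut, gene.has_intron)
    n = int(rng.poisson(lam))
    if n == 0:
        return []
    lo = min(gene.tss, cut_site)
    hi = max(gene.tss, cut_site)
    pos = rng.integers(lo, hi + 1, n)
    strand = opposite_strand(gene.strand)
    return [
        PolymerasePosition(polymerase, gene.chrom, int(p), strand, "dilncRNA")
        for p in pos
    ]


def positions_to_footprints(
    positions: Sequence[PolymerasePosition],
    footprint_lengths: Mapping[int, float],
    genome: Mapping[str, str],
    rng: np.random.Generator,
) -> tuple[list[Footprint], int]:
    """Protected 3'-terminal stumps of the nascent transcripts.

    Each footprint is the last L nt of the transcript, L drawn from the
    footprint-length law; its genomic interval ends at the active site on
    the transcription strand, and its read sequence is the genome slice
    (reverse-complemented for '-' transcription).  Positions whose footprint
    would leave the chromosome are discarded; the count is returned.
    """
    lengths = np.array(sorted(footprint_lengths))
    probs = np.array([footprint_lengths[int(l)] for l in lengths], dtype=float)
    draws = rng.choice(lengths, size=len(positions), p=probs)
    out: list[Footprint] = []
    discarded = 0
    for pp, L in zip(positions, draws):
        L = int(L)
        seq = genome[pp.chrom]
        if pp.transcription_strand == "+":
            start, end = pp.position - L + 1, pp.position + 1
        else:
            start, end = pp.position, pp.position + L
        if start < 0 or end > len(seq):
            discarded += 1
            continue
        read = seq[start:end]
        if pp.transcription_strand == "-":
            read = revcomp(read)
        out.append(
            Footprint(
                GenomicInterval(pp.chrom, start, end, pp.transcription_strand),
                read,
                pp.origin,
                pp.polymerase,
            )
        )
    return out, discarded


def _contamination_footprints(
    config: SimulationConfig, toy: ToyGenome, rng: np.random.Generator
) -> list[Footprint]:
    scale = config.rate_scale
    c = config.contamination
    out: list[Footprint] = []
    # fixed cytoplasmic miRNA, always the same 23-nt sequence
    for _ in range(int(rng.poisson(c.mirna_copies * scale))):
        out.append(
            Footprint(toy.mirna_interval, c.mirna_seq.upper(), "contamination", UNTAGGED)
        )
    # mature rRNA fragments from the rRNA interval, '+' sense
    lengths = np.array(sorted(config.footprint_lengths))
    probs = np.array([config.footprint_lengths[int(l)] for l in lengths], dtype=float)
    n_rrna = int(rng.poisson(c.rrna_copies * scale))
    riv = toy.rrna_interval
    seq = toy.genome[riv.chrom]
    for L in rng.choice(lengths, size=n_rrna, p=probs):
        L = int(L)
        start = int(rng.integers(riv.start, riv.end - L))
        out.append(
            Footprint(
                GenomicInterval(riv.chrom, start, start + L, "+"),
                seq[start : start + L],
                "contamination",
                UNTAGGED,
            )
        )
    # mature spliced mRNA: exon-restricted sense fragments per pol-II gene
    for gene in toy.genes:
        if not _is_polii(config, gene):
            continue
        spec = config.gene_spec(gene.gene_id)
        n_mrna = int(
            rng.poisson(config.mrna_contamination_rate * spec.expression * scale)
        )
        if n_mrna == 0:
            continue
        exon_lens = np.array([e.length for e in gene.exons], dtype=float)
        exon_idx = rng.choice(len(gene.exons), size=n_mrna, p=exon_lens / exon_lens.sum())
        frag_lens = rng.choice(lengths, size=n_mrna, p=probs)
        gseq = toy.genome[gene.chrom]
        for ei, L in zip(exon_idx, frag_lens):
            exon = gene.exons[int(ei)]
            L = int(min(L, exon.length))
            start = int(rng.integers(exon.start, exon.end - L + 1))
            read = gseq[start : start + L]
            if gene.strand == "-":
                read = revcomp(read)
            out.append(
                Footprint(
                    GenomicInterval(gene.chrom, start, start + L, gene.strand),
                    read,
                    "contamination",
                    UNTAGGED,
                )
            )
    return out


def _background_footprints(
    config: SimulationConfig, toy: ToyGenome, rng: np.random.Generator
) -> list[Footprint]:
    n = int(rng.poisson(config.background_rate * config.rate_scale))
    seq = toy.genome[config.chrom]
    lengths = np.array(sorted(config.footprint_lengths))
    probs = np.array([config.footprint_lengths[int(l)] for l in lengths], dtype=float)
    out = []
    for L, strand_bit in zip(
        rng.choice(lengths, size=n, p=probs), rng.integers(0, 2, n)
    ):
        L = int(L)
        start = int(rng.integers(0, len(seq) - L))
        strand = "+" if strand_bit == 0 else "-"
        read = seq[start : start + L]
        if strand == "-":
            read = revcomp(read)
        out.append(
            Footprint(
                GenomicInterval(config.chrom, start, start + L, strand),
                read,
                "background",
                UNTAGGED,
            )
        )
    return out


def build_pool(
    config: SimulationConfig,
    toy: ToyGenome,
    condition: str,
    rng: np.random.Generator,
) -> list[Footprint]:
    """The chromatin-associated footprint pool for one (condition, replicate).

    ``condition`` names the cleaved gene (or "none").  The pool is what an
    input library samples in full; IP libraries are Bernoulli thinnings.
    """
    scale = config.rate_scale
    positions: list[PolymerasePosition] = []
    for gene in toy.genes:
        spec = config.gene_spec(gene.gene_id)
        positions.extend(
            sample_sense_positions(
                gene,
                spec.expression * scale,
                rng,
                pause_weight=config.pause_weight,
                pause_offset=config.pause_offset,
                pause_sd=config.pause_sd,
                polymerase=spec.polymerase,
            )
        )
        if spec.polymerase == "polII":
            positions.extend(
                sample_dilncrna_positions(
                    gene,
                    config.cut_site(gene),
                    config.base_antisense * scale,
                    config.induction_factor,
                    config.spliceosome_boost,
                    is_cut=(condition == gene.gene_id),
                    rng=rng,
                )
            )
    footprints, _ = positions_to_footprints(
        positions, config.footprint_lengths, toy.genome, rng
    )
    footprints.extend(_contamination_footprints(config, toy, rng))
    footprints.extend(_background_footprints(config, toy, rng))
    return footprints


def ip_keep_probability(config: SimulationConfig, footprint_pol: str, tag: str) -> float:
    return config.ip_capture if footprint_pol == tag else config.ip_background


def assemble_library(
    entry: SampleSheetEntry,
    pool: Sequence[Footprint],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[tuple[str, str, str]]:
    """FASTQ records for one library from the shared chromatin pool.

    Input libraries contain the whole pool; IP libraries keep each footprint
    with probability ``ip_capture`` when its polymerase matches the tagged
    one and ``ip_background`` otherwise (contamination and background reads
    are never tag-matched).  Read ids encode the latent origin — downstream
    code must never read them; they exist for test introspection only.
    """
    records = []
    if entry.fraction == "input":
        kept: Iterable[tuple[int, Footprint]] = enumerate(pool)
    else:
        u = rng.random(len(pool))
        kept = (
            (i, fp)
            for i, fp in enumerate(pool)
            if u[i] < ip_keep_probability(config, fp.polymerase, entry.polymerase)
        )
    for i, fp in kept:
        read_id = f"{entry.library_id}|{i}|{fp.origin}|{fp.polymerase}"
        records.append((read_id, fp.sequence, "I" * len(fp.sequence)))
    return records


# ---------------------------------------------------------------------------
# whole-experiment emission


def design_entries(
    config: SimulationConfig, fastq_dir: str = "fastq"
) -> list[SampleSheetEntry]:
    """The full factorial design: polymerase x fraction x condition x replicate."""
    entries = []
    for pol in POLYMERASES:
        for condition in config.cut_targets:
            for rep in range(1, config.n_replicates + 1):
                for fraction in ("input", "IP"):
                    lib = f"{pol}_{fraction}_{condition}cut_r{rep}"
                    entries.append(
                        SampleSheetEntry(
                            library_id=lib,
                            fraction=fraction,
                            polymerase=pol,
                            condition=condition,
                            replicate=rep,
                            fastq_path=f"{fastq_dir}/{lib}.fastq",
                        )
                    )
    return entries


def simulate_experiment(config: SimulationConfig, outdir: str | Path) -> dict:
    """Emit the complete synthetic experiment under ``outdir``.

    Writes genome.fa, annotation.gff3, classes/*.bed, one FASTQ per library,
    samples.tsv and manifest.json (config snapshot, seed and output digests).
    Deterministic: the same (config, seed) yields byte-identical files.
    """
    outdir = Path(outdir)
    (outdir / "fastq").mkdir(parents=True, exist_ok=True)
    (outdir / "classes").mkdir(exist_ok=True)

    toy = build_toy_genome(config)
    write_fasta(toy.genome, outdir / "genome.fa")
    write_gff3(toy.genes, outdir / "annotation.gff3")
    for name, intervals in toy.classes.items():
        write_bed(intervals, outdir / "classes" / f"{name}.bed")

    entries = design_entries(config)
    pools: dict[tuple[str, str, int], list[Footprint]] = {}
    for entry in entries:
        key = (entry.polymerase, entry.condition, entry.replicate)
        if key not in pools:
            pool_rng = substream(
                config.seed, f"pool.{entry.polymerase}.{entry.condition}.{entry.replicate}"
            )
            pools[key] = build_pool(config, toy, entry.condition, pool_rng)
        lib_rng = substream(config.seed, f"ip.{entry.library_id}")
        records = assemble_library(entry, pools[key], config, lib_rng)
        write_fastq(records, outdir / entry.fastq_path)

    write_sample_sheet(entries, outdir / "samples.tsv")

    digests = {}
    for path in sorted(outdir.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            digests[str(path.relative_to(outdir))] = hashlib.sha256(
                path.read_bytes()
            ).hexdigest()
    from . import __version__

    manifest = {
        "tool_version": __version__,
        "seed": config.seed,
        "n_libraries": len(entries),
        "config": _config_snapshot(config),
        "digests": digests,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _config_snapshot(config: SimulationConfig) -> dict:
    snap = asdict(config)
    snap["genes"] = [asdict(g) for g in config.genes]
    return snap


# ---------------------------------------------------------------------------
# latent-count path: locus statistics without read materialisation


def simulate_design_counts(
    config: SimulationConfig,
    seed: int,
    loci: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-library locus counts drawn directly from the latent model.

    For power/calibration studies the locus-level sense and antisense counts
    are the sufficient statistics of the antisense-fraction analysis, so this
    path draws them straight from their Poisson/Binomial laws (sense = nascent
    + spliced-mRNA contamination, IP = Bernoulli thinning of the input pool)
    without materialising reads.  Returns the same tidy table layout as
    :func:`dilncseq.quantify.cut_vs_uncut_table`.
    """
    rng = substream(seed, "design_counts")
    scale = config.rate_scale
    toy_genes = {
        spec.gene_id: spec for spec in config.genes if spec.polymerase == "polII"
    }
    if loci is None:
        loci = [g for g in toy_genes]
    has_intron = {spec.gene_id: spec.n_exons >= 2 for spec in config.genes}

    c = config.contamination
    other_expected = (
        c.mirna_copies + c.rrna_copies + config.background_rate
    ) * scale + sum(
        g.expression * scale for g in config.genes if g.polymerase == "polIII"
    )

    rows = []
    for pol in POLYMERASES:
        for condition in config.cut_targets:
            for rep in range(1, config.n_replicates + 1):
                lib_counts = {}
                for gene_id, spec in toy_genes.items():
                    lam_s = spec.expression * scale
                    lam_m = config.mrna_contamination_rate * spec.expression * scale
                    lam_a = dilncrna_rate(
                        config.base_antisense * scale,
                        config.induction_factor,
                        config.spliceosome_boost,
                        is_cut=(condition == gene_id),
                        has_intron=has_intron[gene_id],
                    )
                    nascent_s = int(rng.poisson(lam_s))
                    mrna_s = int(rng.poisson(lam_m))
                    anti = int(rng.poisson(lam_a))
                    p_n = ip_keep_probability(config, "polII", pol)
                    p_b = config.ip_background
                    lib_counts[gene_id] = {
                        "input": (nascent_s + mrna_s, anti),
                        "IP": (
                            int(rng.binomial(nascent_s, p_n))
                            + int(rng.binomial(mrna_s, p_b)),
                            int(rng.binomial(anti, p_n)),
                        ),
                    }
                # library totals: remaining components as independent Poissons
                other_input = int(rng.poisson(other_expected))
                other_ip = int(
                    rng.binomial(other_input, config.ip_background)
                    if pol == "polII"
                    else rng.poisson(
                        other_expected * config.ip_background
                        + sum(
                            g.expression
                            for g in config.genes
                            if g.polymerase == "polIII"
                        )
                        * scale
                        * (config.ip_capture - config.ip_background)
                    )
                )
                totals = {
                    "input": other_input
                    + sum(s + a for s, a in (v["input"] for v in lib_counts.values())),
                    "IP": other_ip
                    + sum(s + a for s, a in (v["IP"] for v in lib_counts.values())),
                }
                for fraction in ("input", "IP"):
                    lib = f"{pol}_{fraction}_{condition}cut_r{rep}"
                    for locus in loci:
                        s, a = lib_counts[locus][fraction]
                        total = max(totals[fraction], 1)
                        rows.append(
                            {
                                "locus_id": locus,
                                "library_id": lib,
                                "condition": "cut" if condition == locus else "uncut",
                                "cleaved_locus": condition,
                                "replicate": rep,
                                "fraction": fraction,
                                "polymerase": pol,
                                "sense": s,
                                "antisense": a,
                                "total_genome_matching": total,
                                "antisense_fraction": (
                                    a / (s + a) if s + a > 0 else float("nan")
                                ),
                                "antisense_ppm": 1e6 * a / total,
                            }
                        )
    return pd.DataFrame(rows)
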