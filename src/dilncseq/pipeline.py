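"""End-to-end orchestration: align -> count -> test -> terminator scan.

This is the library-level engine behind the command-line interface: it takes
a sample sheet plus genome/annotation (paths or in-memory objects), maps
every library under the exact-match policy, materialises the
reciprocal-control cut-vs-uncut table, runs the replicate-level t-tests per
locus, computes IP/input recovery ratios per transcript class, and scans the
cut gene for pol-III terminator signals.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import align as al
from . import quantify as qt
from . import terminator as tm
from .intervals import GeneModel, GenomicInterval, opposite_strand
from .io_formats import (
    SampleSheetEntry,
    read_bed,
    read_fasta,
    read_gff3,
    read_sample_sheet,
    write_bed,
    write_counts_tsv,
)
from .simulate import substream
from .stats import TTestResult, paired_ttest, welch_ttest

logger = logging.getLogger(__name__)


@dataclass
class PipelineResults:
    mapping_summary: pd.DataFrame
    locus_table: pd.DataFrame
    test_table: pd.DataFrame
    recovery_table: pd.DataFrame
    terminator_report: pd.DataFrame

    def write(self, outdir: str | Path, seed: int | None = None) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_counts_tsv(self.mapping_summary, outdir / "mapping_summary.tsv")
        write_counts_tsv(self.locus_table, outdir / "locus_table.tsv")
        write_counts_tsv(self.test_table, outdir / "tests.tsv")
        write_counts_tsv(self.recovery_table, outdir / "recovery.tsv")
        write_counts_tsv(self.terminator_report, outdir / "terminator.tsv")
        (outdir / "report.txt").write_text(self.report_text())
        from . import __version__

        digests = {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(outdir.glob("*.tsv"))
        }
        manifest = {"tool_version": __version__, "seed": seed, "digests": digests}
        (outdir / "run_manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True)
        )

    def report_text(self) -> str:
        lines = ["dilncseq pipeline report", "=" * 40, ""]
        lines.append("Per-locus cut-vs-uncut tests (two-sided):")
        for _, row in self.test_table.iterrows():
            lines.append(
                f"  {row['locus_id']:>8} {row['polymerase']:>6} {row['fraction']:>5} "
                f"{row['statistic']:>18} {row['test']:>14}: p = {row['p']:.4g}"
            )
        lines.append("")
        lines.append("IP/input recovery ratios (mean over replicate pairs):")
        summary = self.recovery_table.groupby(["class_id", "polymerase"])[
            "recovery"
        ].mean()
        for (class_id, pol), value in summary.items():
            lines.append(f"  {class_id:>8} {pol:>6}: {value:.3f}")
        lines.append("")
        lines.append("Terminator scan of the cut gene (antisense orientation):")
        if self.terminator_report.empty:
            lines.append("  no poly-U run >= threshold found")
        for _, row in self.terminator_report.iterrows():
            lines.append(
                f"  run of {row['run_length']} at {row['chrom']}:{row['start']}-"
                f"{row['end']}  density up/down = {row['density_ratio']:.3f} "
                f"(binomial p = {row['density_p']:.3g})"
            )
        return "\n".join(lines) + "\n"


def align_libraries(
    entries: Sequence[SampleSheetEntry],
    genome: Mapping[str, str],
    seed: int,
    k: int = al.DEFAULT_K,
    fastq_root: str | Path = ".",
) -> tuple[dict[str, list[al.Alignment]], pd.DataFrame]:
    """Size-select and map every library; returns alignments + summary table."""
    index = al.build_index(genome, k=k)
    alignments: dict[str, list[al.Alignment]] = {}
    rows = []
    for entry in entries:
        stats = al.SizeSelectStats()
        reads = al.size_select(
            al.read_fastq(Path(fastq_root) / entry.fastq_path), stats=stats
        )
        alns, summary = al.align_library(
            reads,
            index,
            genome,
            substream(seed, f"align.{entry.library_id}"),
            library_id=entry.library_id,
        )
        alignments[entry.library_id] = alns
        rows.append(
            {
                "library_id": entry.library_id,
                "input_reads": stats.total,
                "size_selected": stats.kept,
                "mapped": summary.mapped,
                "total_genome_matching": summary.total_genome_matching,
            }
        )
    return alignments, pd.DataFrame(rows)


def locus_tests(table: pd.DataFrame) -> pd.DataFrame:
    """Welch (unpaired, on antisense fraction) and paired (on antisense ppm)
    cut-vs-uncut tests for every (locus, polymerase, fraction) cell.

    Loci that are themselves cleavage targets contrast their cut against
    their reciprocal-control (uncut) libraries.  Control loci that are never
    cut contrast the same two library groups (split by which locus was
    cleaved) — the contrast for which no difference is expected.  Cells
    whose statistic is undefined in any replicate (no reads at the locus)
    are reported with p = NA rather than silently dropped — the situation of
    an intronless locus with too few antisense reads.
    """
    rows = []
    for (locus, pol, fraction), cell in table.groupby(
        ["locus_id", "polymerase", "fraction"]
    ):
        if (cell["condition"] == "cut").any():
            cut = cell[cell["condition"] == "cut"].sort_values("replicate")
            uncut = cell[cell["condition"] == "uncut"].sort_values("replicate")
        else:
            groups = sorted(cell["cleaved_locus"].unique())
            if len(groups) != 2:
                continue
            cut = cell[cell["cleaved_locus"] == groups[0]].sort_values("replicate")
            uncut = cell[cell["cleaved_locus"] == groups[1]].sort_values("replicate")
        for statistic, test_fn, test_name in (
            ("antisense_fraction", welch_ttest, "welch_unpaired"),
            ("antisense_ppm", paired_ttest, "paired"),
        ):
            x = cut[statistic].to_numpy(dtype=float)
            y = uncut[statistic].to_numpy(dtype=float)
            if np.isnan(x).any() or np.isnan(y).any():
                result: TTestResult | None = None
            else:
                try:
                    result = test_fn(x, y)
                except ValueError:
                    result = None
            rows.append(
                {
                    "locus_id": locus,
                    "polymerase": pol,
                    "fraction": fraction,
                    "statistic": statistic,
                    "test": test_name,
                    "n": min(len(x), len(y)),
                    "mean_cut": (
                        float(np.nanmean(x))
                        if len(x) and not np.isnan(x).all()
                        else float("nan")
                    ),
                    "mean_uncut": (
                        float(np.nanmean(y))
                        if len(y) and not np.isnan(y).all()
                        else float("nan")
                    ),
                    "t": result.t if result else float("nan"),
                    "df": result.df if result else float("nan"),
                    "p": result.p if result else float("nan"),
                    "degenerate": bool(result.degenerate) if result else True,
                }
            )
    return pd.DataFrame(rows)


def recovery_ratios(
    entries: Sequence[SampleSheetEntry],
    alignments: Mapping[str, list[al.Alignment]],
    totals: Mapping[str, int],
    classes: Mapping[str, Sequence[GenomicInterval]],
) -> pd.DataFrame:
    """Per-class IP/input recovery for every IP library and its paired input."""
    by_key = {
        (e.polymerase, e.condition, e.replicate, e.fraction): e for e in entries
    }
    rows = []
    for entry in entries:
        if entry.fraction != "IP":
            continue
        pair = by_key.get((entry.polymerase, entry.condition, entry.replicate, "input"))
        if pair is None:
            raise ValueError(f"IP library {entry.library_id} lacks a paired input")
        for class_id, intervals in classes.items():
            rr = qt.recovery(
                class_id,
                list(intervals),
                alignments[entry.library_id],
                totals[entry.library_id],
                alignments[pair.library_id],
                totals[pair.library_id],
            )
            rows.append(
                {
                    "class_id": class_id,
                    "polymerase": entry.polymerase,
                    "condition": entry.condition,
                    "replicate": entry.replicate,
                    "ip_ppm": rr.ip_ppm,
                    "input_ppm": rr.input_ppm,
                    "recovery": float("nan") if rr.recovery is None else rr.recovery,
                }
            )
    return pd.DataFrame(rows)


def terminator_scan(
    genome: Mapping[str, str],
    gene: GeneModel,
    alignments: Sequence[al.Alignment],
    min_run: int = tm.DEFAULT_MIN_RUN,
    exclusion: int = tm.DEFAULT_EXCLUSION,
    hairpin_window: int = 60,
    cut_site: int | None = None,
) -> pd.DataFrame:
    """Scan a gene for antisense-orientation pol-III terminators and compare
    antisense read density across each, as a tidy report table.

    When ``cut_site`` is known (the analyst designed the break), the density
    comparison is clipped to the antisense transcription unit between the
    TSS and the cut, so the segment beyond the break — where no antisense
    transcript exists — does not dilute the downstream density.
    """
    anti = opposite_strand(gene.strand)
    if cut_site is None:
        unit = gene
    else:
        lo = min(gene.tss, cut_site)
        hi = max(gene.tss, cut_site) + 1
        unit = GeneModel(
            gene.gene_id,
            GenomicInterval(gene.chrom, lo, hi, gene.strand),
        )
    sites = tm.find_terminators(genome, unit.span, anti, min_run=min_run)
    rows = []
    for site in sites:
        hairpin = tm.find_hairpin(genome, site, window=hairpin_window)
        dens = tm.density_across_terminator(
            alignments, unit, site, exclusion=exclusion, strand_filter=anti
        )
        rows.append(
            {
                "gene_id": gene.gene_id,
                "chrom": site.position.chrom,
                "start": site.position.start,
                "end": site.position.end,
                "transcription_strand": site.transcription_strand,
                "run_length": site.run_length,
                "hairpin_stem": hairpin.stem_length if hairpin else 0,
                "hairpin_loop": hairpin.loop_length if hairpin else 0,
                "hairpin_offset": hairpin.offset if hairpin else -1,
                "upstream_density": dens.upstream_density,
                "downstream_density": dens.downstream_density,
                "density_ratio": float("nan") if dens.ratio is None else dens.ratio,
                "density_p": float("nan") if dens.p is None else dens.p,
            }
        )
    columns = [
        "gene_id", "chrom", "start", "end", "transcription_strand", "run_length",
        "hairpin_stem", "hairpin_loop", "hairpin_offset", "upstream_density",
        "downstream_density", "density_ratio", "density_p",
    ]
    return pd.DataFrame(rows, columns=columns)


def run_pipeline(
    entries: Sequence[SampleSheetEntry],
    genome: Mapping[str, str],
    genes: Sequence[GeneModel],
    classes: Mapping[str, Sequence[GenomicInterval]],
    seed: int,
    loci: Sequence[str] | None = None,
    flank: int = 0,
    fastq_root: str | Path = ".",
    terminator_gene: str | None = None,
    cut_sites: Mapping[str, int] | None = None,
    outdir: str | Path | None = None,
) -> PipelineResults:
    """The full analysis on an existing experiment (simulated or real).

    ``loci`` restricts the cut-vs-uncut analysis (default: all annotated
    genes); ``terminator_gene`` names the gene scanned for antisense pol-III
    terminators (default: the first condition label in the design).
    """
    alignments, mapping_summary = align_libraries(
        entries, genome, seed, fastq_root=fastq_root
    )
    totals = dict(
        zip(mapping_summary["library_id"], mapping_summary["total_genome_matching"])
    )
    gene_by_id = {g.gene_id: g for g in genes}
    if loci is None:
        loci = [g.gene_id for g in genes]

    counts = [
        qt.count_locus(
            alignments[e.library_id],
            gene_by_id[locus],
            totals[e.library_id],
            library_id=e.library_id,
            flank=flank,
        )
        for e in entries
        for locus in loci
    ]
    locus_table = qt.cut_vs_uncut_table(counts, list(entries))
    test_table = locus_tests(locus_table)
    recovery_table = recovery_ratios(entries, alignments, totals, classes)

    if terminator_gene is None:
        terminator_gene = entries[0].condition
    term_gene = gene_by_id[terminator_gene]
    # pool the pol-II input libraries of the condition where this gene is
    # cut: the input contains every footprint the IP sampled (IP reads are a
    # thinned subset, so adding them would double-count footprints and
    # overdisperse the density test), and the strand filter keeps sense
    # contamination out
    pooled = [
        aln
        for e in entries
        if e.polymerase == "polII"
        and e.fraction == "input"
        and e.condition == terminator_gene
        for aln in alignments[e.library_id]
    ]
    terminator_report = terminator_scan(
        genome,
        term_gene,
        pooled,
        cut_site=(cut_sites or {}).get(terminator_gene),
    )

    results = PipelineResults(
        mapping_summary=mapping_summary,
        locus_table=locus_table,
        test_table=test_table,
        recovery_table=recovery_table,
        terminator_report=terminator_report,
    )
    if outdir is not None:
        results.write(outdir, seed=seed)
        for e in entries:
            write_bed(
                alignments[e.library_id],
                Path(outdir) / f"alignments_{e.library_id}.bed",
            )
    return results


def run_pipeline_from_paths(
    sample_sheet: str | Path,
    genome_fa: str | Path,
    annotation_gff3: str | Path,
    class_beds: Mapping[str, str | Path] | None,
    seed: int,
    outdir: str | Path | None = None,
    **kwargs,
) -> PipelineResults:
    """File-path convenience wrapper around :func:`run_pipeline`."""
    entries = read_sample_sheet(sample_sheet)
    genome = read_fasta(genome_fa)
    genes = read_gff3(annotation_gff3)
    classes = {
        name: read_bed(path) for name, path in (class_beds or {}).items()
    }
    if not classes:  # default classes from the annotation itself
        classes = {
            "exon": [e for g in genes for e in g.exons],
            "intron": [i for g in genes for i in g.introns],
        }
    return run_pipeline(
        entries,
        genome,
        genes,
        classes,
        seed,
        fastq_root=Path(sample_sheet).parent,
        outdir=outdir,
        **kwargs,
    )
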