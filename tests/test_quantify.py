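import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dilncseq import (
    Alignment,
    GeneModel,
    GenomicInterval,
    LocusStrandCounts,
    SampleSheetEntry,
    antisense_fraction,
    antisense_ppm,
    count_locus,
    cut_vs_uncut_table,
    recovery,
)


def aln(start, end, strand, chrom="c", rid="r"):
    return Alignment(rid, GenomicInterval(chrom, start, end, strand), 1)


GENE = GeneModel(
    "g",
    GenomicInterval("c", 100, 500, "+"),
    (GenomicInterval("c", 100, 500, "+"),),
)


class TestCountLocus:
    def test_same_strand_read_inside_gene_is_sense(self):
        c = count_locus([aln(200, 224, "+")], GENE, 100)
        assert (c.sense, c.antisense) == (1, 0)

    def test_opposite_strand_read_touching_one_nt_of_flank(self):
        c = count_locus([aln(500, 524, "-")], GENE, 100, flank=1)
        assert (c.sense, c.antisense) == (0, 1)
        # without the flank the same read does not count
        c0 = count_locus([aln(500, 524, "-")], GENE, 100, flank=0)
        assert (c0.sense, c0.antisense) == (0, 0)

    def test_no_overlapping_reads(self):
        c = count_locus([aln(600, 624, "+"), aln(10, 34, "-")], GENE, 100)
        assert (c.sense, c.antisense) == (0, 0)

    def test_negative_flank_rejected(self):
        with pytest.raises(ValueError):
            count_locus([], GENE, 0, flank=-1)

    def test_agrees_with_brute_force_interval_scan(self, rng):
        for _ in range(20):
            start = int(rng.integers(0, 800))
            gene = GeneModel(
                "g",
                GenomicInterval("c", start, start + int(rng.integers(50, 200)), "+"),
            )
            alns = [
                aln(s, s + 24, "+" if rng.random() < 0.5 else "-")
                for s in rng.integers(0, 1000, 200)
            ]
            flank = int(rng.integers(0, 30))
            c = count_locus(alns, gene, 1000, flank=flank)
            lo, hi = gene.span.start - flank, gene.span.end + flank
            sense = sum(
                1 for a in alns
                if a.interval.start < hi and a.interval.end > lo and a.strand == "+"
            )
            anti = sum(
                1 for a in alns
                if a.interval.start < hi and a.interval.end > lo and a.strand == "-"
            )
            assert (c.sense, c.antisense) == (sense, anti)


class TestAntisenseStatistics:
    def test_fraction_arithmetic(self):
        c = LocusStrandCounts("g", "l", sense=9, antisense=1, total_genome_matching=100)
        assert antisense_fraction(c) == pytest.approx(0.1)

    def test_zero_coverage_is_flagged_undefined_not_zero(self):
        c = LocusStrandCounts("g", "l", 0, 0, 100)
        assert antisense_fraction(c) is None

    def test_ppm_normalisation(self):
        c = LocusStrandCounts("g", "l", 0, 5, 1_000_000)
        assert antisense_ppm(c) == pytest.approx(5.0)
        z = LocusStrandCounts("g", "l", 3, 0, 1000)
        assert antisense_ppm(z) == 0.0

    def test_ppm_requires_positive_total(self):
        c = LocusStrandCounts("g", "l", 0, 0, 0)
        with pytest.raises(ValueError):
            antisense_ppm(c)

    def test_locus_reads_cannot_exceed_library_total(self):
        with pytest.raises(ValueError):
            LocusStrandCounts("g", "l", 60, 50, 100)

    @given(
        sense=st.integers(0, 1000),
        antisense=st.integers(0, 1000),
        extra=st.integers(0, 1000),
    )
    @settings(max_examples=200, deadline=None)
    def test_fraction_bounds_and_monotonicity(self, sense, antisense, extra):
        total = sense + antisense + extra + 1
        c = LocusStrandCounts("g", "l", sense, antisense, total)
        f = antisense_fraction(c)
        if f is None:
            assert sense == antisense == 0
        else:
            assert 0.0 <= f <= 1.0
            more = LocusStrandCounts("g", "l", sense, antisense + 1, total + 1)
            assert antisense_fraction(more) >= f

    def test_ppm_conserved_over_a_read_partition(self, rng):
        # partition all mapped reads into disjoint bins: per-bin antisense ppm
        # computed on the antisense-only library sums to exactly 1e6
        starts = rng.integers(0, 10_000, 500)
        alns = [aln(int(s), int(s) + 24, "-") for s in starts]
        edges = [0, 2000, 5000, 10_024]
        total = len(alns)
        ppm_sum = 0.0
        for lo, hi in zip(edges, edges[1:]):
            n = sum(1 for a in alns if lo <= a.interval.start < hi)
            ppm_sum += 1e6 * n / total
        assert ppm_sum == pytest.approx(1e6)


class TestRecovery:
    CLS = [GenomicInterval("c", 100, 500, "+")]

    def test_identical_libraries_give_unit_recovery(self):
        reads = [aln(150, 174, "+"), aln(300, 324, "-"), aln(700, 724, "+")]
        rr = recovery("cls", self.CLS, reads, 3, reads, 3)
        assert rr.recovery == pytest.approx(1.0)

    def test_zero_input_signal_is_flagged_undefined(self):
        rr = recovery("cls", self.CLS, [aln(150, 174, "+")], 10, [aln(700, 724, "+")], 10)
        assert rr.recovery is None

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            recovery("cls", [], [], 1, [], 1)

    def test_enrichment_reflected_in_ratio(self):
        ip = [aln(150, 174, "+")] * 8 + [aln(700, 724, "+")] * 2
        inp = [aln(150, 174, "+")] * 2 + [aln(700, 724, "+")] * 8
        rr = recovery("cls", self.CLS, ip, 10, inp, 10)
        assert rr.recovery == pytest.approx(4.0)


def _design(loci=("gA", "gB"), reps=3):
    entries = []
    for pol in ("polII",):
        for cond in loci:
            for rep in range(1, reps + 1):
                for fraction in ("input", "IP"):
                    entries.append(
                        SampleSheetEntry(
                            f"{pol}_{fraction}_{cond}_r{rep}",
                            fraction, pol, cond, rep, "x.fastq",
                        )
                    )
    return entries


class TestCutVsUncutTable:
    def _counts(self, entries, loci=("gA", "gB")):
        return [
            LocusStrandCounts(locus, e.library_id, 50, 5, 1000)
            for e in entries
            for locus in loci
        ]

    def test_reciprocal_design_row_combinatorics(self):
        entries = _design()
        table = cut_vs_uncut_table(self._counts(entries), entries)
        # per fraction: 2 loci x 2 conditions x 3 replicates = 12 rows
        for fraction in ("input", "IP"):
            assert len(table[table["fraction"] == fraction]) == 12
        cell = table[(table["locus_id"] == "gA") & (table["fraction"] == "IP")]
        assert sorted(cell["condition"]) == ["cut"] * 3 + ["uncut"] * 3

    def test_swapping_locus_labels_swaps_condition_labels(self):
        entries = _design()
        table = cut_vs_uncut_table(self._counts(entries), entries)
        a = table[(table["locus_id"] == "gA") & (table["cleaved_locus"] == "gB")]
        b = table[(table["locus_id"] == "gB") & (table["cleaved_locus"] == "gB")]
        assert set(a["condition"]) == {"uncut"}
        assert set(b["condition"]) == {"cut"}

    def test_row_values_recompute_from_raw_counts(self):
        entries = _design(reps=2)
        counts = [
            LocusStrandCounts("gA", e.library_id, 40 + i, 3 * i + 1, 900 + i)
            for i, e in enumerate(entries)
        ]
        table = cut_vs_uncut_table(counts, entries)
        for c in counts:
            row = table[
                (table["library_id"] == c.library_id) & (table["locus_id"] == "gA")
            ].iloc[0]
            assert row["antisense_fraction"] == pytest.approx(
                c.antisense / (c.sense + c.antisense)
            )
            assert row["antisense_ppm"] == pytest.approx(
                1e6 * c.antisense / c.total_genome_matching
            )

    def test_missing_replicate_pairing_rejected(self):
        entries = _design()
        # drop one cut-side library for gA entirely
        broken = [e for e in entries if e.library_id != "polII_IP_gA_r2"]
        counts = [
            LocusStrandCounts("gA", e.library_id, 50, 5, 1000) for e in broken
        ]
        with pytest.raises(ValueError, match="pairing"):
            cut_vs_uncut_table(counts, broken)

    def test_undefined_fraction_propagates_as_nan(self):
        entries = _design(reps=2)
        counts = [
            LocusStrandCounts("gA", e.library_id, 0, 0, 1000) for e in entries
        ]
        table = cut_vs_uncut_table(counts, entries)
        assert table["antisense_fraction"].isna().all()
        assert (table["antisense_ppm"] == 0).all()
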