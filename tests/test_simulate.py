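import collections
import json

import numpy as np
import pytest
from scipy import stats as sps

from dilncseq import (
    GeneModel,
    GenomicInterval,
    SampleSheetEntry,
    SimulationConfig,
    positions_to_footprints,
    revcomp,
    sample_dilncrna_positions,
    sample_sense_positions,
    simulate_experiment,
)
from dilncseq.simulate import (
    GeneSpec,
    assemble_library,
    build_pool,
    dilncrna_rate,
)


def plus_gene(start=100, length=1000, exons=1):
    span = GenomicInterval("c", start, start + length, "+")
    if exons == 1:
        ex = (span,)
    else:
        third = length // 3
        ex = (
            GenomicInterval("c", start, start + third, "+"),
            GenomicInterval("c", start + 2 * third, start + length, "+"),
        )
    return GeneModel("g", span, ex)


class TestConfigValidation:
    def test_overlapping_genes_rejected(self):
        genes = (
            GeneSpec("a", 0, 1000, "+", 1, 10.0),
            GeneSpec("b", 500, 1000, "+", 1, 10.0),
        )
        with pytest.raises(ValueError, match="overlap"):
            SimulationConfig(genes=genes, cut_targets={})

    def test_ip_background_must_be_below_capture(self):
        with pytest.raises(ValueError, match="ip_background"):
            SimulationConfig(ip_capture=0.1, ip_background=0.5)

    def test_footprint_law_must_be_on_23_to_26(self):
        with pytest.raises(ValueError, match="23"):
            SimulationConfig(footprint_lengths={20: 1.0})

    def test_cut_offset_must_fall_inside_the_gene(self):
        with pytest.raises(ValueError, match="cut offset"):
            SimulationConfig(cut_targets={"geneA": 99999})


class TestToyGenome:
    def test_annotation_has_all_configured_genes(self, small_config, toy):
        assert [g.gene_id for g in toy.genes] == [
            s.gene_id for s in small_config.genes
        ]

    def test_cut_gene_pairs_intron_containing_with_intronless(self, toy):
        assert toy.gene("geneA").has_intron
        assert not toy.gene("geneB").has_intron

    def test_planted_a8_in_second_intron_of_cut_gene(self, small_config, toy):
        gene = toy.gene("geneA")
        intron = gene.introns[1]
        seq = toy.genome[gene.chrom]
        runs = [
            i
            for i in range(intron.start, intron.end - 7)
            if seq[i : i + 8] == "A" * 8
        ]
        assert len(runs) == 1
        # and it is the only A8/T8 anywhere in the genome
        assert seq.count("A" * 8) == 1
        assert seq.count("T" * 8) == 0

    def test_class_collections_cover_exons_introns_and_trna(self, toy):
        assert toy.classes["trna"] == [toy.gene("trnaA").span]
        assert set(toy.classes["cds"]) >= set(toy.gene("geneA").exons)
        assert set(toy.classes["intron"]) >= set(toy.gene("geneA").introns)

    def test_same_seed_twice_is_byte_identical(self, tmp_path):
        cfg = SimulationConfig(seed=5, library_depth=300, n_replicates=1)
        m1 = simulate_experiment(cfg, tmp_path / "a")
        m2 = simulate_experiment(cfg, tmp_path / "b")
        assert m1["digests"] == m2["digests"]

    def test_manifest_records_config_and_digests(self, experiment_dir):
        manifest = json.loads((experiment_dir / "manifest.json").read_text())
        assert manifest["n_libraries"] == 24
        assert manifest["config"]["seed"] == 11
        assert "genome.fa" in manifest["digests"]


class TestSensePositions:
    def test_zero_rate_gives_empty_list(self, rng):
        assert sample_sense_positions(plus_gene(), 0.0, rng) == []

    def test_no_pausing_is_uniform_over_the_span(self, rng):
        gene = plus_gene(start=0, length=2000)
        pos = sample_sense_positions(gene, 10_000, rng, pause_weight=0.0)
        xs = np.array([p.position for p in pos])
        stat = sps.kstest(xs, sps.uniform(0, 2000).cdf)
        assert stat.pvalue > 0.01

    def test_full_pausing_concentrates_near_tss_offset(self, rng):
        gene = plus_gene(start=500, length=2000)
        pos = sample_sense_positions(
            gene, 2000, rng, pause_weight=1.0, pause_offset=40, pause_sd=5.0
        )
        xs = np.array([p.position for p in pos])
        centre = 500 + 40
        assert np.mean(np.abs(xs - centre) <= 15) >= 0.95  # 3 sigma

    def test_minus_strand_pause_sits_near_its_tss(self, rng):
        span = GenomicInterval("c", 0, 1000, "-")
        gene = GeneModel("g", span, (span,))
        pos = sample_sense_positions(
            gene, 2000, rng, pause_weight=1.0, pause_offset=40, pause_sd=5.0
        )
        xs = np.array([p.position for p in pos])
        assert np.mean(np.abs(xs - (999 - 40)) <= 15) >= 0.95
        assert all(p.transcription_strand == "-" for p in pos)


class TestDilncrnaPositions:
    def test_zero_baseline_uncut_is_empty(self, rng):
        gene = plus_gene()
        assert (
            sample_dilncrna_positions(gene, 600, 0.0, 10.0, 5.0, False, rng) == []
        )

    def test_intronless_rate_is_independent_of_the_intron_boost(self):
        assert dilncrna_rate(2.0, 5.0, 100.0, True, has_intron=False) == 10.0
        assert dilncrna_rate(2.0, 5.0, 100.0, False, has_intron=True) == 2.0

    def test_mean_count_ratio_recovers_the_intron_boost(self, rng):
        intron_gene = plus_gene(exons=2)
        flat_gene = plus_gene(exons=1)
        f_intron = 3.0
        counts = {"intron": [], "flat": []}
        for _ in range(1000):
            counts["intron"].append(
                len(sample_dilncrna_positions(intron_gene, 900, 2.0, 4.0, f_intron, True, rng))
            )
            counts["flat"].append(
                len(sample_dilncrna_positions(flat_gene, 900, 2.0, 4.0, f_intron, True, rng))
            )
        ratio = np.mean(counts["intron"]) / np.mean(counts["flat"])
        assert ratio == pytest.approx(f_intron, rel=0.15)

    def test_positions_span_tss_to_cut_site_antisense(self, rng):
        gene = plus_gene(start=100, length=1000)
        pos = sample_dilncrna_positions(gene, 600, 500.0, 1.0, 1.0, False, rng)
        xs = [p.position for p in pos]
        assert min(xs) >= 100 and max(xs) <= 600
        assert all(p.transcription_strand == "-" for p in pos)
        assert all(p.origin == "dilncRNA" for p in pos)


class TestFootprints:
    GENOME = {"c": "ACGTACGTGGATCCTTAGCAGCGGTACGATCGGATTACCAGTCGACCGTA" * 3}

    def test_plus_strand_footprint_ends_at_active_site(self, rng):
        from dilncseq.simulate import PolymerasePosition

        pp = PolymerasePosition("polII", "c", 40, "+", "sense")
        fps, dropped = positions_to_footprints([pp], {23: 1.0}, self.GENOME, rng)
        (fp,) = fps
        assert dropped == 0
        assert (fp.interval.start, fp.interval.end) == (18, 41)
        assert fp.sequence == self.GENOME["c"][18:41]

    def test_minus_strand_footprint_is_reverse_complemented(self, rng):
        from dilncseq.simulate import PolymerasePosition

        pp = PolymerasePosition("polII", "c", 40, "-", "dilncRNA")
        fps, _ = positions_to_footprints([pp], {23: 1.0}, self.GENOME, rng)
        (fp,) = fps
        assert (fp.interval.start, fp.interval.end) == (40, 63)
        assert fp.sequence == revcomp(self.GENOME["c"][40:63])

    def test_out_of_bounds_positions_are_discarded_and_counted(self, rng):
        from dilncseq.simulate import PolymerasePosition

        pps = [
            PolymerasePosition("polII", "c", 5, "+", "sense"),  # runs off the left
            PolymerasePosition("polII", "c", 40, "+", "sense"),
        ]
        fps, dropped = positions_to_footprints(pps, {26: 1.0}, self.GENOME, rng)
        assert dropped == 1 and len(fps) == 1

    def test_all_footprint_lengths_within_protected_range(self, small_config, toy, rng):
        pool = build_pool(small_config, toy, "geneA", rng)
        lengths = {fp.interval.length for fp in pool}
        assert lengths <= set(range(23, 27))


class TestAssembleLibrary:
    def _pool(self, config, toy, rng):
        return build_pool(config, toy, "geneA", rng)

    def test_pure_capture_keeps_exactly_the_tagged_footprints(self, toy, rng):
        cfg = SimulationConfig(
            seed=1, library_depth=2000, ip_capture=1.0, ip_background=0.0
        )
        pool = self._pool(cfg, toy, rng)
        entry = SampleSheetEntry("ip", "IP", "polII", "geneA", 1, "x.fastq")
        reads = assemble_library(entry, pool, cfg, rng)
        tagged = sum(1 for fp in pool if fp.polymerase == "polII")
        assert len(reads) == tagged
        assert all(rid.split("|")[3] == "polII" for rid, _, _ in reads)

    def test_ip_reads_are_a_subset_of_the_input_pool(self, small_config, toy, rng):
        pool = self._pool(small_config, toy, rng)
        entry_in = SampleSheetEntry("in", "input", "polII", "geneA", 1, "x.fastq")
        entry_ip = SampleSheetEntry("ip", "IP", "polII", "geneA", 1, "y.fastq")
        input_reads = assemble_library(entry_in, pool, small_config, rng)
        ip_reads = assemble_library(entry_ip, pool, small_config, rng)
        input_multiset = collections.Counter(seq for _, seq, _ in input_reads)
        ip_multiset = collections.Counter(seq for _, seq, _ in ip_reads)
        assert all(ip_multiset[s] <= input_multiset[s] for s in ip_multiset)
        assert len(input_reads) == len(pool)

    def test_contamination_thinned_at_background_rate(self, toy, rng):
        cfg = SimulationConfig(seed=2, library_depth=20_000)
        pool = self._pool(cfg, toy, rng)
        entry = SampleSheetEntry("ip", "IP", "polII", "geneA", 1, "x.fastq")
        reads = assemble_library(entry, pool, cfg, rng)
        contam_in = sum(1 for fp in pool if fp.origin == "contamination")
        contam_ip = sum(1 for rid, _, _ in reads if rid.split("|")[2] == "contamination")
        lo, hi = sps.binom.interval(0.999, contam_in, cfg.ip_background)
        assert lo <= contam_ip <= hi

    def test_wrong_polymerase_ip_keeps_locus_reads_at_background_rate(self, toy, rng):
        # a pol-III IP of a pol-II-only locus leaves its read distribution as
        # thinned input: expected locus reads = p_b * input locus reads
        cfg = SimulationConfig(seed=3, library_depth=20_000)
        pool = self._pool(cfg, toy, rng)
        gene = toy.gene("geneD")
        entry = SampleSheetEntry("ip3", "IP", "polIII", "geneA", 1, "x.fastq")
        reads = assemble_library(entry, pool, cfg, rng)
        in_locus = sum(
            1 for fp in pool if fp.interval.overlaps(gene.span) and fp.polymerase == "polII"
        )
        ip_ids = {rid for rid, _, _ in reads}
        ip_locus = sum(
            1
            for i, fp in enumerate(pool)
            if fp.interval.overlaps(gene.span)
            and fp.polymerase == "polII"
            and f"{entry.library_id}|{i}|{fp.origin}|{fp.polymerase}" in ip_ids
        )
        lo, hi = sps.binom.interval(0.999, in_locus, cfg.ip_background)
        assert lo <= ip_locus <= hi
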