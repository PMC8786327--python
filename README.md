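# dilncseq

Quantification of DNA-break-induced antisense transcription from
polymerase-specific nascent-RNA sequencing (NET-seq), with a full synthetic
experiment generator for testing every stage without external data.

## The scientific problem

When a DNA double-strand break occurs inside a transcribed gene, local
transcription can initiate *at the break* and run antisense toward the
gene's transcription start site, producing a damage-induced long non-coding
RNA (dilncRNA). Together with the normal sense transcript this forms
double-stranded RNA, the precursor of damage-induced siRNAs. Two questions
drive the analysis this package implements:

1. **Which polymerase transcribes the dilncRNA?** NET-seq libraries are
   made by immunoprecipitating an epitope-tagged RNA polymerase (II or III)
   from chromatin after a brief nuclease digestion; the 23–26 nt RNA stump
   protected by the polymerase is sequenced. Comparing IP against the
   chromatin input, strand by strand, reveals which polymerase carries the
   antisense transcript.
2. **Does the spliceosome stimulate dilncRNA synthesis?** Breaks placed
   downstream of introns induce more antisense transcription than breaks in
   intronless genes, which the analysis resolves by cutting an
   intron-containing and an intronless locus in turn, each serving as the
   other's uncut control (the reciprocal-control design).

## Statistics at the core

For a locus with strand-resolved read counts, two normalised statistics are
computed per library:

- **antisense fraction** `antisense / (sense + antisense)` — antisense
  activity relative to the locus's total transcriptional output; tested
  cut-vs-uncut with Welch's unpaired unequal-variance t-test (n = 3
  replicates).
- **antisense ppm** `10⁶ · antisense / total genome-matching reads` —
  tested with a paired t-test across replicates.

Polymerase specificity of the IP is summarised per transcript class as the
**recovery ratio** `IP ppm / input ppm`. Finally, a pol-III involvement
check scans the antisense transcription unit for poly-U terminators (a
genomic A₈ run for an antisense transcript in a `+` gene, preceded in the
transcript by a hairpin-forming inverted repeat) and compares antisense
read density upstream vs downstream of the run with an exact binomial test,
excluding a ~20 nt dropout window around the homopolymer.

Mapping follows the footprint policy: perfect full-length matches only,
both strands; a read matching several loci is reported exactly once, at a
uniformly random hit under an explicit seed.

## Worked example

`examples/` contains one short script per capability. Simulating the
default 24-library experiment (two tagged polymerases × input/IP × two
cleavage conditions × three replicates, ~20 000 reads per library) and
running the cut-vs-uncut tests:

```
$ python examples/01_simulate_experiment.py
wrote 24 libraries under scratch/example_experiment
...
$ python examples/03_cut_vs_uncut_tests.py
locus_id          statistic           test    mean_cut  mean_uncut        p
   geneA antisense_fraction welch_unpaired    0.010851    0.001008 0.007193
   geneA      antisense_ppm         paired 2273.674488  215.046118 0.005851
   geneB antisense_fraction welch_unpaired    0.004290    0.001178 0.025314
   geneB      antisense_ppm         paired  895.780239  247.842190 0.072344
   geneC antisense_fraction welch_unpaired    0.001613    0.001790 0.794223
   geneD antisense_fraction welch_unpaired    0.000424    0.000426 0.993146
```

Cutting the intron-containing gene (geneA) raises its pol-II IP antisense
fraction about tenfold (p ≈ 0.007); the intronless gene (geneB) responds
more weakly, and the never-cut control loci (geneC, geneD) show nothing.
Recovery ratios confirm the IP specificity — and the terminator scan finds
the planted A₈ with unchanged density across it, as expected when pol-II,
not pol-III, transcribes the antisense RNA:

```
$ python examples/04_recovery_ratios.py
cds       polII          1.271
          polIII         0.066
intron    polII          1.674
trna      polIII        10.298
$ python examples/05_terminator_scan.py
U8 terminator for the '-' transcript at toy1:4800-4808
  upstream hairpin: stem 6 bp, loop 4 nt, offset 7 nt
  antisense read density up/down = 0.90 (binomial p = 0.807)
```

The same pipeline is available from the shell:

```
dilncseq simulate --seed 2 outdir
dilncseq run --sheet outdir/samples.tsv --genome outdir/genome.fa \
    --annotation outdir/annotation.gff3 --classes outdir/classes \
    --seed 2 results/
```

## Layout

- `src/dilncseq/` — the library: `io_formats` (FASTA/FASTQ/GFF3/BED/TSV),
  `simulate` (the generative model), `align` (exact-match mapping),
  `quantify` (strand-resolved statistics), `stats` (t-tests, binomial
  density test), `terminator` (poly-U scan, hairpin, density comparison),
  `pipeline` (orchestration), `cli`.
- `examples/` — one narrative script per capability.
- `tests/` — unit, property and whole-pipeline suites.
- `docs/methods.md` — the model, its assumptions and numerical choices.
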