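# Methods

## The generative model

The simulator emulates a polymerase-specific nascent-RNA (NET-seq)
experiment on a ~30 kb toy genome carrying five planted genes: an
intron-containing cleavage target (`geneA`, 3 exons), an intronless
reciprocal target (`geneB`), two never-cut controls (`geneC`, `geneD`) and
a pol-III transcribed tRNA-like locus (`trnaA`). All coordinates are
0-based half-open; GFF3 converts at the I/O boundary.

**Nascent sense transcription.** Each gene contributes
`Poisson(expression)` engaged polymerases per library. Active-site
positions follow a two-component mixture: with probability `pause_weight`
(default 0.5) a truncated normal centred `pause_offset` (40 nt) past the
TSS with `pause_sd` 15 nt — promoter-proximal pausing — otherwise uniform
over the gene body. Each polymerase yields one read: the 3′-terminal
`L ∈ {23..26}` nt of its nascent transcript (the nuclease-protected
footprint; uniform length law by default), whose genomic interval ends at
the active site and whose sequence is reverse-complemented for `−`-strand
transcription.

**Break-induced antisense transcription.** At each pol-II locus a second,
antisense population initiates: `Poisson(λ)` polymerases uniform between
the TSS and the (actual or hypothetical) cut site, transcribing opposite to
the gene. The uniform position law is the simplest one consistent with an
antisense transcript that starts at the break and extends to the TSS.
`λ = base_antisense` (default 2.0) at an uncut locus; cutting multiplies it
by `induction_factor` (5.0) and, only when the gene has at least one
intron, by `spliceosome_boost` (2.0) — so the default cut induction is
10-fold for the intron-containing target and 5-fold for the intronless
one. The antisense polymerase is pol-II: which polymerase carries the
transcript is exactly what the downstream analysis must be able to decide.

**Contamination and background.** Input libraries carry what chromatin
preparations really contain: a fixed 23-nt cytoplasmic miRNA sequence
(planted in the genome so it genome-matches), fragments of an rRNA
interval, mature spliced-mRNA fragments restricted to exons
(`mrna_contamination_rate` × expression per gene), and a uniform
genome-wide background. None of these carry a polymerase tag.

**Immunoprecipitation as Bernoulli thinning.** An IP library keeps each
footprint of its input pool independently: with probability `ip_capture`
(0.8) when the footprint's polymerase matches the tagged one, `ip_background`
otherwise. This makes the IP read multiset a subset of the input pool and
gives every recovery ratio a closed form: for a transcript class whose
reads all carry tag *t*,

```
E[recovery] = p_keep(t) / Σ_g p_keep(g)·w_g
```

where `w_g` are the pool's tag proportions. The defaults
`ip_capture = 0.8`, `ip_background = 0.005` were fixed once from the
structure the experiment exhibits: the antisense *fraction* is invariant
under uniform thinning, so the wrong-polymerase IP can only appear
negative—as it does in the real assay—if its absolute locus counts are
noise-dominated. With these defaults the pol-II IP detects the cut-locus
induction in ~100% of repeated experiments at 10⁵ reads/library while the
pol-III IP and the control loci stay at the ~5% false-positive floor.
`base_antisense` is deliberately small relative to sense expression
(~0.1%); real dilncRNA levels are far below mRNA transcription and the
experiment's power comes from the contrast, not the absolute level.

**Determinism.** All randomness derives from one root seed through named
substreams (`genome`, `pool.<pol>.<condition>.<rep>`, `ip.<library>`,
`align.<library>`), so any stage can be regenerated independently and the
whole experiment is byte-reproducible (manifest with SHA-256 digests).

**What the simulator does not model** — and hence what passing tests do
not show about real data: sequencing errors and quality variation, PCR
duplicates, mappability structure of a real genome (repeats beyond the
deliberately planted duplicate loci in tests), nuclease sequence bias,
splicing intermediates, and any repair kinetics. The IP is a single
per-read Bernoulli; real IPs have locus-correlated capture.

## Alignment policy

Reads are mapped under the small-footprint policy: perfect full-length
matches only, on either strand; reads containing N never map (the
strictest reading of "no mismatches"); a read with several perfect hits is
reported exactly once at a uniformly random hit, with the candidate count
recorded. The implementation is a k-mer hash (k = 12 by default, below the
20 nt size-selection minimum) over the forward genome with full-string
verification of every candidate, so seed-only false positives are
impossible; an exhaustive all-positions scan ships alongside as the test
oracle. Size selection keeps 20–28 nt reads inclusive, mirroring the gel
purification step.

## Quantification choices

- A read counts for a locus when it overlaps the (flank-extended) gene
  span by ≥ 1 nt; default flank 0. Reads overlapping two genes count for
  each independently — a caveat for convergent gene pairs.
- Undefined statistics (a locus with zero reads; a recovery with zero
  input signal) propagate as explicit flags/NA, never as zeros, so
  low-coverage loci are visible rather than silently averaged.
- Per-locus p-values are reported raw: a handful of named loci are tested,
  and no multiple-testing correction is applied.
- Never-cut control loci have no cut/uncut split; their contrast compares
  the same libraries grouped by which *other* locus was cleaved — the
  contrast for which no difference is expected.

## Hypothesis tests

Welch's statistic `t = (x̄−ȳ)/√(s²ₓ/nₓ+s²ᵧ/nᵧ)` with Welch–Satterthwaite
degrees of freedom, and the paired one-sample t on differences, are
implemented directly; only the t distribution function comes from scipy,
whose full test routines serve as independent oracles in the test suite.
All p-values are two-sided. Degenerate inputs (zero variance) are flagged
and reported at their limit values (p = 1 for identical samples, p = 0 for
a noiseless nonzero shift). The terminator density comparison uses the
exact two-sided binomial test (minimum-likelihood method) of the upstream
read count against the length-proportional null.

A calibration note: Welch's p-values at n = 3 are only approximately
uniform under the null — a property of the Welch–Satterthwaite
approximation itself, detectable at 10⁴ replicates. The suite therefore
checks null uniformity where the null is exact (paired t at any n, Welch at
n = 30) and checks the n = 3 behaviour as a type-I-error band ([0.03,
0.08] at α = 0.05).

## Terminator scan

A pol-III terminator is a run of ≥ `min_run` (default 8) uridines in the
nascent transcript: genomic T-runs terminate a `+` transcript, A-runs a
`−` transcript. Runs are reported maximally. The upstream secondary
structure element is the best inverted repeat (stem ≥ 5 bp Watson–Crick,
G·U optional and off by default, loop ≤ 10 nt) within 60 nt upstream in
transcript orientation — a structural search, not a free-energy fold,
which suffices to flag a "potential" element. When a greedy stem extension
swallows a self-complementary loop, the stem backs off to the longest
length leaving a legal loop.

The density comparison splits the antisense transcription unit at the run,
excluding 20 nt (total, centred on the run, always covering it) of
technical dropout, and compares strand-filtered reads per nucleotide with
the binomial test. When the cut position is known the segments are clipped
to the TSS–cut unit; otherwise to the gene span. The pipeline pools the
pol-II *input* libraries of the cut condition for this scan: the input
contains every footprint the IP sampled, and adding the IP reads would
double-count footprints and overdisperse the test.

## Problem sizes

The default end-to-end runs use ~20 000 reads per library (24 libraries),
where every qualitative contrast of the design is already decisive. The
repeated-experiment calibration of the break-induction design (100
simulated experiments at 10⁵ reads/library) runs on the latent locus
counts — Poisson sense/antisense draws with Bernoulli IP thinning — which
are the sufficient statistics of the antisense-fraction analysis; the
read-level path (footprint sequences through the aligner) is exercised
end to end at the 20k depth and in the recovery-ratio comparison at 10⁵
reads.

## Known limitations

- The exact-match policy discards any read touching a variant or error;
  real libraries need the mismatch tolerance of a production aligner.
- Recovery ratios for mixed-tag classes (e.g. exons carrying both nascent
  and mature-mRNA reads) are blends; the closed form applies per tag
  component.
- The hairpin search scores stem length only — no thermodynamics, no
  bulges or mismatched stems.
- `cut_vs_uncut_table` requires a complete replicate pairing and refuses
  partial designs rather than imputing.
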