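"""IP/input recovery ratios: the polymerase-specificity readout.

For each transcript class (CDS exons, introns, the tRNA-like pol-III locus)
the recovery is the class's reads-per-million in the IP divided by the same
quantity in the paired input.  A successful polymerase-specific IP enriches
that polymerase's transcript classes and depletes the others.
"""

from pathlib import Path

from dilncseq import SimulationConfig, run_pipeline_from_paths, simulate_experiment

outdir = Path("scratch/example_experiment")
if not (outdir / "genome.fa").exists():
    simulate_experiment(SimulationConfig(seed=2, library_depth=20_000), outdir)

results = run_pipeline_from_paths(
    outdir / "samples.tsv",
    outdir / "genome.fa",
    outdir / "annotation.gff3",
    {n: outdir / "classes" / f"{n}.bed" for n in ("cds", "intron", "trna")},
    seed=2,
    loci=["geneA"],
    terminator_gene="geneA",
)

summary = results.recovery_table.groupby(["class_id", "polymerase"])["recovery"].mean()
print(summary.round(3).to_string())
# cds/intron classes recover in the pol-II IP (ratio > 1) but not in the
# pol-III IP; the tRNA-like locus shows the opposite pattern.
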