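from pathlib import Path

import numpy as np
import pytest

from dilncseq import (
    SimulationConfig,
    build_toy_genome,
    run_pipeline_from_paths,
    simulate_experiment,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A light experiment: full 24-library design at ~20k reads/library."""
    return SimulationConfig(seed=11, library_depth=20_000)


@pytest.fixture(scope="session")
def toy(small_config):
    return build_toy_genome(small_config)


@pytest.fixture(scope="session")
def experiment_dir(small_config, tmp_path_factory) -> Path:
    outdir = tmp_path_factory.mktemp("experiment")
    simulate_experiment(small_config, outdir)
    return outdir


@pytest.fixture(scope="session")
def pipeline_results(small_config, experiment_dir, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("results")
    cfg = small_config
    toy = build_toy_genome(cfg)
    cut_sites = {g: cfg.cut_site(toy.gene(g)) for g in cfg.cut_targets}
    return run_pipeline_from_paths(
        experiment_dir / "samples.tsv",
        experiment_dir / "genome.fa",
        experiment_dir / "annotation.gff3",
        {
            name: experiment_dir / "classes" / f"{name}.bed"
            for name in ("cds", "intron", "trna")
        },
        seed=11,
        loci=["geneA", "geneB", "geneC", "geneD"],
        terminator_gene="geneA",
        cut_sites=cut_sites,
        outdir=outdir,
    ), outdir


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
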