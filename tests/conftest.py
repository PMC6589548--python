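import numpy as np
import pandas as pd
import pytest

from editome.simulate import SimulationConfig, simulate_dataset


def tiny_config(**overrides) -> SimulationConfig:
    """A small but structurally complete study for fast unit tests."""
    base = dict(
        seed=11,
        n_chroms=1,
        chrom_length=150_000,
        n_genes=6,
        n_repeats=40,
        n_editing_sites=150,
        n_stages=9,
        replicates_per_stage=2,
        n_het_snps=20,
        n_hom_snps=10,
        n_background_sites=50,
        mean_depth=40,
        n_homopolymers_per_chrom=10,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("tiny_sim")
    return simulate_dataset(tiny_config(), outdir)


@pytest.fixture(scope="session")
def tiny_genome(tiny_dataset):
    return tiny_dataset.reference.sequences()


@pytest.fixture
def rng():
    return np.random.default_rng(0)
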