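import warnings

import numpy as np
import pytest

import h3turnover as h
from h3turnover.simulate import SimConfig, simulate_dataset

warnings.filterwarnings("ignore", category=UserWarning)


def small_config(seed: int = 0, **overrides) -> SimConfig:
    """A desk-scale genome for cheap unit tests."""
    defaults = dict(
        seed=seed, genome_length=2_000_000, n_chromosomes=2, n_genes=24,
        n_enhancers=12, n_trna=4, n_rrna=2, n_line=4, n_sine=4, n_satellite=2,
        telomere_length=30_000, sites_per_telomere=4, pericentromere_length=20_000,
        depth_per_library=40_000,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def small_dataset():
    return simulate_dataset(small_config(seed=3))


@pytest.fixture(scope="session")
def default_dataset():
    """The full-scale study-condition simulation (seed 1)."""
    return simulate_dataset(h.SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_result(default_dataset):
    ds = default_dataset
    return h.run_analysis(ds.chip_libs, ds.input_lib, ds.genome.genes,
                          ds.genome.chromosomes, ds.genome.repeat_blocks,
                          ds.mark_sets, ds.mark_libs, ds.rna_lib)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
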