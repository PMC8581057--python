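import numpy as np
import pytest

from rrscan.genome import GenomeLayout
from rrscan.simulate import SimulationConfig, simulate_experiment


@pytest.fixture(scope="session")
def layout():
    return GenomeLayout({"chr1": 100_000, "chr2": 49_999})


@pytest.fixture(scope="session")
def dataset():
    """One shared simulated experiment at the study replicate count."""
    return simulate_experiment(SimulationConfig(seed=7, replicates_per_group=3))


@pytest.fixture(scope="session")
def small_config():
    """A fast, small configuration for structural tests."""
    return SimulationConfig(
        seed=3, n_chroms=1, chrom_length=3_000_000, n_genes=60, n_repeats=20,
        replicates_per_group=2, n_ega_on_blocks=1, n_ega_off_blocks=1,
        n_pff_off_blocks=0, n_pff_on_blocks=0,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_experiment(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
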