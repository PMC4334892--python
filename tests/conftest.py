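import numpy as np
import pytest

from methdrift.simulate import SimConfig, generate_dataset, null_config


@pytest.fixture(scope="session")
def small_dataset():
    """A small planted cohort shared across read-only tests."""
    cfg = SimConfig(
        n_samples=100, n_chromosomes=2, probes_per_chromosome=800, n_blocks=2, seed=7
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def null_dataset():
    """A global-null cohort (no drift, no blocks, no composition signal)."""
    cfg = null_config(
        n_samples=100, n_chromosomes=2, probes_per_chromosome=800, seed=11
    )
    return generate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
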