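import numpy as np
import pytest

from tfbind.simulate import SimConfig, generate


@pytest.fixture(scope="session")
def sim_data():
    """Default synthetic fixture, shared across tests (read-only)."""
    return generate(SimConfig(seed=11))


@pytest.fixture(scope="session")
def small_sim_data():
    """Smaller, faster fixture for pipeline-level unit tests."""
    return generate(
        SimConfig(seed=7, n_chroms=2, chrom_length=100_000, n_sites=30, n_decoys=30)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
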