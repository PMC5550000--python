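import numpy as np
import pytest

from mapit import simulate_genotypes


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_panel():
    """A 60 x 40 standardized genotype panel shared across unit tests."""
    return simulate_genotypes(60, 40, seed=7)


@pytest.fixture(scope="session")
def medium_panel():
    """A 200 x 150 panel for tests that need some statistical resolution."""
    return simulate_genotypes(200, 150, seed=11)
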