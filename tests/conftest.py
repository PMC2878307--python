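import numpy as np
import pytest

from alunuc.simulate import SimConfig, simulate_all


@pytest.fixture(scope="session")
def small_sim():
    """300-kb synthetic data set shared by fast closed-loop tests."""
    return simulate_all(SimConfig(genome_len=300_000, seed=11))


@pytest.fixture(scope="session")
def profile_sim():
    """1-Mb synthetic data set for nucleosome metaprofile recovery."""
    return simulate_all(SimConfig(genome_len=1_000_000, seed=3))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(42)
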