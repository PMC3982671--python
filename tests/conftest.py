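import numpy as np
import pytest
from hypothesis import settings

from kinfitness.config import SimulationConfig
from kinfitness.simulate import simulate_dataset

settings.register_profile("ci", deadline=None, max_examples=50, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig()


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A desk-scale population: fast, but with enough helpers to summarize."""
    return SimulationConfig(n_years=8, n_pairs_per_year=40)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config, seed=101)


@pytest.fixture(scope="session")
def default_dataset(default_config):
    return simulate_dataset(default_config, seed=7)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
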