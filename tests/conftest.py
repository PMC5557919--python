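import numpy as np
import pytest

from alascan.synth import SimulationConfig


@pytest.fixture(scope="session")
def tiny_config() -> SimulationConfig:
    """A small but classifiable library (>= 10 strains, fast wells)."""
    return SimulationConfig(seed=7, n_mutants=12, event_count_per_well=300)


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    """The full study-scale configuration."""
    return SimulationConfig(seed=1)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(123)
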