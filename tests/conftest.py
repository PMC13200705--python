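import numpy as np
import pytest

from cortexkymo.simulate import SimulationConfig, build_geometry


@pytest.fixture(scope="session")
def budded_config() -> SimulationConfig:
    """Default medium-budded cell, short movie, noise on."""
    return SimulationConfig(n_frames=30, seed=11)


@pytest.fixture(scope="session")
def budded_geometry(budded_config):
    return build_geometry(budded_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
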