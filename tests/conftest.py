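import numpy as np
import pytest

from timecellchain import CellParams, IntegratorConfig, NetworkConfig, NoiseConfig


@pytest.fixture(scope="session")
def params() -> CellParams:
    return CellParams()


@pytest.fixture(scope="session")
def integ() -> IntegratorConfig:
    return IntegratorConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)


@pytest.fixture(scope="session")
def small_chain_config() -> NetworkConfig:
    """A short chain that still shows the transmission-delay mechanism."""
    return NetworkConfig(n_cells=8)


@pytest.fixture(scope="session")
def no_noise() -> NoiseConfig:
    return NoiseConfig(sd_gD=0.0, sd_gExc=0.0, poisson=False)
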