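import numpy as np
import pytest

from rhizocohere.centrifuge import SpinProtocol
from rhizocohere.mechanistic import FlumeConfig, MechParams, RootGeometry
from rhizocohere.synth import PROFILES, NoiseSpec


@pytest.fixture(scope="session")
def protocol() -> SpinProtocol:
    return SpinProtocol()


@pytest.fixture(scope="session")
def profiles():
    return PROFILES


@pytest.fixture(scope="session")
def geometry() -> RootGeometry:
    return RootGeometry()


@pytest.fixture(scope="session")
def flume() -> FlumeConfig:
    return FlumeConfig()


@pytest.fixture
def quiet_noise() -> NoiseSpec:
    """Deterministic, noise-free generator settings."""
    return NoiseSpec(seed=0, trace_noise_sd=0.0, erosion_lognorm_sigma=0.0, mass_cv=0.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
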