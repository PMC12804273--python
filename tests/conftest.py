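import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hypomem.core import ModelParameters, OxygenProtocol
from hypomem.solver import Grids, InitialCondition

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def params() -> ModelParameters:
    return ModelParameters()


@pytest.fixture(scope="session")
def cyclic_protocol() -> OxygenProtocol:
    return OxygenProtocol(period=10.0, bias=0.5)


@pytest.fixture(scope="session")
def coarse_grids() -> Grids:
    """Small mesh (dx=0.125, dmu=0.02) that still contains mu_hn0 exactly."""
    return Grids(N=81, M=51)


@pytest.fixture(scope="session")
def default_grids() -> Grids:
    return Grids()


@pytest.fixture(scope="session")
def ic() -> InitialCondition:
    return InitialCondition()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
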