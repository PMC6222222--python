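import numpy as np
import pytest
from hypothesis import settings

from ohsmarket.params import EconomyParams, EWAParams, default_calibration
from ohsmarket.experiments import SMOKE_OVERRIDES

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def econ() -> EconomyParams:
    return EconomyParams()


@pytest.fixture
def ewa() -> EWAParams:
    return EWAParams()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def smoke_config():
    """Reduced-size run configuration for fast structural checks."""
    return default_calibration(seed=7, **SMOKE_OVERRIDES)
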