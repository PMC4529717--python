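import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ckst.exchange import ExchangeSystem

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def nominal_system() -> ExchangeSystem:
    """Healthy-heart system at 3 T: kf 0.32/s, intrinsic T1 7.9/2.2 s."""
    return ExchangeSystem()


@pytest.fixture
def hf_system() -> ExchangeSystem:
    """Heart-failure-range forward rate, other parameters nominal."""
    return ExchangeSystem(kf=0.21)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
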