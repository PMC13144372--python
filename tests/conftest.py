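import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from betamito import SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def config():
    """Default configuration (fitted health-coupling parameter set)."""
    return SimConfig()


@pytest.fixture
def short_config():
    """Small horizon for fast structural checks."""
    return SimConfig(t_end=200.0, record_interval=5.0)
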