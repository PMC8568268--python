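import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from scotomap.geometry import DEFAULT_SCREEN
from scotomap.observer import DEFAULT_OBSERVER, ScotomaObserver

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def screen():
    return DEFAULT_SCREEN


@pytest.fixture
def default_observer():
    return DEFAULT_OBSERVER


@pytest.fixture
def sharp_observer():
    """Noise-free observer with a hard scotoma boundary."""
    return ScotomaObserver(
        boundary_slope=0.0,
        lapse_rate=0.0,
        guess_rate=0.0,
        fixation_jitter_sd=0.0,
        click_error_sd=0.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
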