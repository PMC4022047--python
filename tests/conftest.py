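import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "det",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


def gaussian(mz, center, height, sigma):
    return height * np.exp(-0.5 * ((mz - center) / sigma) ** 2)


@pytest.fixture
def dense_axis():
    """A dense uniform axis around m/z 1000 (step 0.01 Th)."""
    return np.arange(980.0, 1020.0, 0.01)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
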