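import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from retphen.behavior import BoxGeometry

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def box() -> BoxGeometry:
    """Example arena: 100x50 cm, 10 cm doorway centered on the divider."""
    return BoxGeometry(doorway_width=10.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
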