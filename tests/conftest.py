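import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from micropharm import MetaboliteProfile, build_network


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_microbe_profiles():
    """The worked two-microbe instance with hand-computable extents."""
    return [
        MetaboliteProfile("A", {"m1", "m2"}, {"m3"}),
        MetaboliteProfile("B", {"m2", "m4"}, {"m1"}),
    ]


@pytest.fixture
def two_microbe_network(two_microbe_profiles):
    return build_network(two_microbe_profiles)
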