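import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")

from dcssdnet import ArchConfig, DCSSDNet  # noqa: E402


@pytest.fixture(scope="session")
def model299():
    """Default-architecture detector (299 input), built once per session."""
    return DCSSDNet(ArchConfig(seed=0))


@pytest.fixture(scope="session")
def forward299(model299):
    """One real forward pass of the default backbone on a random frame."""
    rng = np.random.default_rng(42)
    x = rng.random((1, 299, 299, 3), dtype=np.float32)
    outputs = model299.backbone.forward(x)
    return x, outputs


@pytest.fixture(scope="session")
def model149():
    """Reduced-input detector used where a cheap forward pass suffices."""
    return DCSSDNet(ArchConfig(input_size=149, seed=0))
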