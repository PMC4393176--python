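import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def circle(radius: float, n: int = 64, centre=(0.0, 0.0)) -> np.ndarray:
    """Regular n-gon approximating a circle, CCW, vertices off the axes."""
    th = (np.arange(n) + 0.5) * 2 * np.pi / n
    return np.column_stack(
        [centre[0] + radius * np.cos(th), centre[1] + radius * np.sin(th)]
    )


@pytest.fixture
def make_circle():
    return circle
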