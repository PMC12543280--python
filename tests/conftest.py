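import numpy as np
import pytest

from smstoich import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """Fast config: short traces, one field."""
    return SimulationConfig(frames=200, n_bio=1, n_tech=1, spots_per_field=50)


def staircase(levels, lengths, noise_sd=0.0, rng=None):
    """Piecewise-constant trace from plateau levels and lengths."""
    x = np.concatenate([np.full(n, float(v)) for v, n in zip(levels, lengths)])
    if noise_sd > 0:
        x = x + rng.normal(0.0, noise_sd, size=len(x))
    return x


@pytest.fixture
def make_staircase():
    return staircase
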