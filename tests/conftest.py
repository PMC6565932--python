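import numpy as np
import pytest

from hbggm.core import TimeSeriesPanel
from hbggm.simulate import circle_precision, sample_timeseries


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def circle6():
    return circle_precision(6)


@pytest.fixture
def small_panel(rng):
    """Two subjects, p=4, n=60, drawn from a shared sparse precision."""
    Om = circle_precision(4)
    return TimeSeriesPanel([sample_timeseries(Om, 60, rng) for _ in range(2)])


def random_pd(p, rng, cond=3.0):
    """A random symmetric positive definite matrix with bounded conditioning."""
    A = rng.normal(size=(p, p))
    M = A @ A.T + cond * np.eye(p)
    return (M + M.T) / 2.0


@pytest.fixture
def random_pd_factory(rng):
    return lambda p: random_pd(p, rng)
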