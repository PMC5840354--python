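import numpy as np
import pytest

from phytojip.curves import InductionCurve
from phytojip.ojip import OJIPMarkers


@pytest.fixture
def log_grid():
    """Standard 118-point log-spaced grid, 10 us to 1 s."""
    return np.logspace(-5, 0, 118)


@pytest.fixture
def reference_markers():
    """The worked marker set: Fo=500, F300=900, FJ=1500, FI=2000, Fm=2500."""
    return OJIPMarkers(fo=500.0, f300=900.0, fj=1500.0, fi=2000.0,
                       fm=2500.0, t_fm=0.3)


@pytest.fixture
def make_curve(log_grid):
    """Factory for an InductionCurve from a value function of time."""

    def _make(fn, times=None, label="test", metadata=None):
        t = log_grid if times is None else np.asarray(times, dtype=float)
        return InductionCurve(t, np.asarray(fn(t), dtype=float),
                              label, metadata or {})

    return _make
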