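import numpy as np
import pytest

from osmokin import (
    KineticPoint,
    KineticSeries,
    ODMeasurement,
)


@pytest.fixture
def measurement():
    """A physically consistent mid-treatment observation (w0 = 10 g)."""
    return ODMeasurement(
        variety="orange", temperature=20.0, time=3.0, replicate=1,
        w0=10.0, u0=2.0, u=3.0, ww0=8.0, ww=4.0, aw=0.65)


@pytest.fixture
def peleg_series_factory():
    """Noiseless Peleg series builder: (k1, k2, times) -> KineticSeries."""

    def make(k1, k2, times=(0.0, 1.0, 3.0, 5.0), kind="WL"):
        pts = tuple(
            KineticPoint(t=t, Y=0.0 if t == 0 else t / (k1 + k2 * t))
            for t in times)
        return KineticSeries(variety="v", temperature=20.0, kind=kind, points=pts)

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
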