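"""Mass-transfer arithmetic, series assembly and input validation."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from osmokin import (
    ODMeasurement,
    build_kinetic_series,
    compute_moisture_ratio,
    compute_solid_gain,
    compute_water_loss,
)
from osmokin.mass_transfer import (
    DegenerateSeriesError,
    GroupingError,
    InsufficientDataError,
    InvalidMeasurementError,
    MassBalanceWarning,
    NegativeTransferWarning,
)


def _m(w0=10.0, u0=2.0, u=3.0, ww0=None, ww=4.0, **kw):
    if ww0 is None:
        ww0 = w0 - u0
    defaults = dict(variety="orange", temperature=20.0, time=1.0, replicate=1)
    defaults.update(kw)
    return ODMeasurement(w0=w0, u0=u0, u=u, ww0=ww0, ww=ww, **defaults)


@pytest.mark.parametrize(
    "w0, u0, u, expected",
    [
        (10.0, 2.0, 2.0, 0.0),      # no solid uptake
        (10.0, 2.0, 3.0, 0.1),
        (20.0, 4.0, 7.4, 0.17),
    ],
)
def test_solid_gain_arithmetic(w0, u0, u, expected):
    assert compute_solid_gain(_m(w0=w0, u0=u0, u=u, ww=w0 - u0)) == pytest.approx(expected)


@pytest.mark.parametrize(
    "w0, ww0, ww, expected",
    [
        (10.0, 8.0, 8.0, 0.0),      # no water removed
        (10.0, 8.0, 4.0, 0.4),
        (10.0, 8.0, 0.27, 0.773),   # the maximum-WL regime
    ],
)
def test_water_loss_arithmetic(w0, ww0, ww, expected):
    assert compute_water_loss(_m(w0=w0, u0=w0 - ww0, ww0=ww0, ww=ww)) == pytest.approx(expected)


def test_negative_transfer_warned_not_clipped():
    with pytest.warns(NegativeTransferWarning):
        sg = compute_solid_gain(_m(u=1.9))
    assert sg == pytest.approx(-0.01)


@pytest.mark.parametrize(
    "M, M0, Me, expected",
    [(2.0, 2.0, 0.5, 1.0), (0.5, 2.0, 0.5, 0.0), (1.5, 2.0, 0.5, 2.0 / 3.0)],
)
def test_moisture_ratio(M, M0, Me, expected):
    assert compute_moisture_ratio(M, M0, Me) == pytest.approx(expected)


def test_moisture_ratio_degenerate():
    with pytest.raises(DegenerateSeriesError):
        compute_moisture_ratio(1.0, 0.5, 0.5)


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(w0=0.0), dict(w0=-1.0), dict(u0=0.0), dict(u0=11.0),
        dict(u=-0.1), dict(ww=-1.0), dict(aw=1.2), dict(aw=0.0),
        dict(replicate=0), dict(time=-1.0),
    ],
)
def test_invalid_measurements_rejected(kwargs):
    with pytest.raises(InvalidMeasurementError):
        _m(**kwargs)


def test_mass_balance_violation_warns():
    with pytest.warns(MassBalanceWarning):
        _m(ww0=7.5)  # u0 + ww0 = 9.5 != 10


@given(
    w0=st.floats(1.0, 100.0),
    u0_frac=st.floats(0.05, 0.6),
    delta_u=st.floats(0.0, 5.0),
    delta_w=st.floats(0.0, 0.99),
)
@settings(max_examples=200, deadline=None)
def test_physical_bounds_property(w0, u0_frac, delta_u, delta_w):
    """For consistent inputs with ww <= ww0, u >= u0: SG >= 0, WL in [0, ww0/w0]."""
    u0 = u0_frac * w0
    ww0 = w0 - u0
    m = _m(w0=w0, u0=u0, u=u0 + delta_u, ww0=ww0, ww=ww0 * (1 - delta_w))
    assert compute_solid_gain(m) >= 0
    assert 0 <= compute_water_loss(m) <= ww0 / w0 + 1e-12


@given(c=st.floats(0.1, 10.0), delta=st.floats(0.01, 3.0))
@settings(max_examples=100, deadline=None)
def test_numerator_linearity(c, delta):
    """Scaling (u - u0) by c scales SG by exactly c."""
    m1 = _m(u=2.0 + delta, ww=8.0)
    m2 = _m(u=2.0 + c * delta, ww=8.0)
    assert compute_solid_gain(m2) == pytest.approx(c * compute_solid_gain(m1), rel=1e-12)


class TestBuildKineticSeries:
    def _reps(self, values_by_time, **kw):
        out = []
        for t, vals in values_by_time.items():
            for i, wl in enumerate(vals, start=1):
                out.append(_m(time=t, replicate=i, ww=8.0 - 10.0 * wl, **kw))
        return out

    def test_replicates_averaged_with_sd(self):
        ms = self._reps({1.0: [0.39, 0.40, 0.41], 3.0: [0.5] * 3, 5.0: [0.6] * 3})
        series = build_kinetic_series(ms, "WL")
        p1 = series.points[1]
        assert p1.t == 1.0
        assert p1.Y == pytest.approx(0.40)
        assert p1.sd == pytest.approx(np.std([0.39, 0.40, 0.41], ddof=1))
        assert series.points[2].sd == pytest.approx(0.0)

    def test_anchor_injected(self):
        ms = self._reps({1.0: [0.4], 3.0: [0.5], 5.0: [0.6]})
        series = build_kinetic_series(ms, "WL")
        assert series.points[0].t == 0.0 and series.points[0].Y == 0.0

    def test_empty_input(self):
        with pytest.raises(InsufficientDataError):
            build_kinetic_series([], "WL")

    def test_too_few_times(self):
        ms = self._reps({1.0: [0.4]})
        with pytest.raises(InsufficientDataError):
            build_kinetic_series(ms, "WL")

    def test_mixed_conditions_rejected(self):
        ms = self._reps({1.0: [0.4], 3.0: [0.5]})
        ms += self._reps({5.0: [0.6]}, temperature=35.0)
        with pytest.raises(GroupingError):
            build_kinetic_series(ms, "WL")

    def test_moisture_kind_has_no_anchor(self):
        ms = self._reps({0.0: [0.0], 1.0: [0.4], 3.0: [0.5], 5.0: [0.6]})
        series = build_kinetic_series(ms, "moisture")
        assert series.points[0].Y == pytest.approx(8.0 / 3.0)  # ww/u at t = 0
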