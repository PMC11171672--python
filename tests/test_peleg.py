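"""Peleg kinetics: recovery oracles, derived quantities, invariants."""

import numpy as np
import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

from osmokin import (
    KineticPoint,
    KineticSeries,
    PelegFit,
    fit_peleg,
    fit_peleg_moisture,
    peleg_equilibrium,
    peleg_initial_rate,
    predict_peleg,
)
from osmokin.mass_transfer import DegenerateSeriesError, InsufficientDataError
from osmokin.peleg import FitQualityWarning, InvalidFitError


def _grid_search_sse(t, Y, lo=0.01, hi=50.0, n=60, zooms=4):
    """Independent brute-force oracle: zooming grid search for min SSE."""
    lo1, hi1, lo2, hi2 = lo, hi, lo, hi
    best = None
    for _ in range(zooms):
        k1g = np.linspace(lo1, hi1, n)
        k2g = np.linspace(lo2, hi2, n)
        K1, K2 = np.meshgrid(k1g, k2g, indexing="ij")
        pred = t[None, None, :] / (K1[..., None] + K2[..., None] * t[None, None, :])
        sse = np.sum((Y[None, None, :] - pred) ** 2, axis=-1)
        i, j = np.unravel_index(np.argmin(sse), sse.shape)
        best = (k1g[i], k2g[j], sse[i, j])
        w1 = (hi1 - lo1) / (n - 1)
        w2 = (hi2 - lo2) / (n - 1)
        lo1, hi1 = max(lo, k1g[i] - 2 * w1), k1g[i] + 2 * w1
        lo2, hi2 = max(lo, k2g[j] - 2 * w2), k2g[j] + 2 * w2
    return best


@pytest.mark.parametrize("k1, k2", [(2.0, 1.0), (0.676, 1.180), (27.766, 4.553)])
def test_noiseless_recovery(peleg_series_factory, k1, k2):
    """Fits on exact Peleg curves recover the generating constants."""
    fit = fit_peleg(peleg_series_factory(k1, k2))
    assert fit.k1 == pytest.approx(k1, rel=1e-6)
    assert fit.k2 == pytest.approx(k2, rel=1e-6)


def test_grid_search_oracle_equivalence(rng):
    """Fitted SSE matches an independent zooming grid search."""
    t = np.array([1.0, 3.0, 5.0])
    Y = np.array([0.33, 0.58, 0.68]) + rng.normal(0, 0.01, 3)
    pts = (KineticPoint(0.0, 0.0),) + tuple(KineticPoint(ti, yi) for ti, yi in zip(t, Y))
    fit = fit_peleg(KineticSeries("v", 20.0, "WL", pts))
    pred = t / (fit.k1 + fit.k2 * t)
    sse_fit = float(np.sum((Y - pred) ** 2))
    _, _, sse_grid = _grid_search_sse(t, Y)
    assert sse_fit <= sse_grid * (1 + 1e-3)


def test_linearization_consistency(peleg_series_factory):
    """On noiseless data, OLS on t/Y = k1 + k2*t gives the same constants."""
    k1t, k2t = 1.595, 1.220
    series = peleg_series_factory(k1t, k2t)
    fit = fit_peleg(series)
    t, Y = series.t[1:], series.Y[1:]
    A = np.column_stack([np.ones(t.size), t])
    (k1_lin, k2_lin), *_ = np.linalg.lstsq(A, t / Y, rcond=None)
    assert fit.k1 == pytest.approx(k1_lin, rel=1e-6)
    assert fit.k2 == pytest.approx(k2_lin, rel=1e-6)


def test_all_zero_series_degenerate(peleg_series_factory):
    pts = tuple(KineticPoint(t, 0.0) for t in (0.0, 1.0, 3.0, 5.0))
    with pytest.raises(DegenerateSeriesError):
        fit_peleg(KineticSeries("v", 20.0, "WL", pts))


def test_missing_anchor_rejected():
    pts = tuple(KineticPoint(t, t / (2 + t)) for t in (1.0, 3.0, 5.0))
    with pytest.raises(InsufficientDataError):
        fit_peleg(KineticSeries("v", 20.0, "WL", pts))


class TestDerivedQuantities:
    def test_predict_examples(self):
        fit = PelegFit.from_constants(0.676, 1.180)
        assert predict_peleg(fit, 0.0) == 0.0
        assert predict_peleg(fit, 5.0) == pytest.approx(0.7604, abs=1e-4)
        # large-time limit approaches 1/k2
        assert predict_peleg(fit, 1e9) == pytest.approx(1 / 1.180, rel=1e-6)

    def test_predict_negative_time_rejected(self):
        with pytest.raises(ValueError):
            predict_peleg(PelegFit.from_constants(1.0, 1.0), -0.1)

    @pytest.mark.parametrize(
        "k1, expected", [(1.767, 0.566), (27.766, 0.036), (1.0, 1.0)])
    def test_initial_rate(self, k1, expected):
        fit = PelegFit.from_constants(k1, 1.0)
        assert round(peleg_initial_rate(fit), 3) == expected

    @pytest.mark.parametrize(
        "k2, expected", [(1.073, 0.932), (6.866, 0.146), (1.0, 1.0)])
    def test_equilibrium(self, k2, expected):
        fit = PelegFit.from_constants(1.0, k2)
        assert round(peleg_equilibrium(fit), 3) == expected

    def test_nonpositive_constants_rejected(self):
        with pytest.raises(InvalidFitError):
            PelegFit.from_constants(-1.0, 1.0)


@given(k1=st.floats(0.1, 30.0), k2=st.floats(0.5, 8.0))
@settings(max_examples=50, deadline=None,
          suppress_health_check=[HealthCheck.function_scoped_fixture])
def test_reparameterization_identity(peleg_series_factory, k1, k2):
    """initial_rate*k1 = 1 and equilibrium*k2 = 1 to machine precision."""
    fit = fit_peleg(peleg_series_factory(k1, k2))
    assert fit.initial_rate * fit.k1 == pytest.approx(1.0, abs=1e-15)
    assert fit.equilibrium * fit.k2 == pytest.approx(1.0, abs=1e-15)


def test_prediction_monotone_concave_bounded(peleg_series_factory):
    fit = fit_peleg(peleg_series_factory(1.767, 1.073))
    t = np.linspace(0, 50, 400)
    y = predict_peleg(fit, t)
    assert np.all(np.diff(y) >= 0)
    assert np.all(np.diff(y, 2) <= 1e-12)
    assert np.all(y <= 1.0 / fit.k2 + 1e-12)


class TestMoistureForm:
    def _series(self, xw0, k1, k2, sign=-1.0, times=(0.0, 1.0, 3.0, 5.0)):
        pts = tuple(
            KineticPoint(t, xw0 + sign * (0.0 if t == 0 else t / (k1 + k2 * t)))
            for t in times)
        return KineticSeries("v", 20.0, "moisture", pts)

    def test_noiseless_desorption_recovery(self):
        fit = fit_peleg_moisture(self._series(4.0, 2.0, 1.0), "desorption")
        assert fit.k1 == pytest.approx(2.0, rel=1e-6)
        assert fit.k2 == pytest.approx(1.0, rel=1e-6)
        assert fit.xw0 == 4.0
        assert fit.equilibrium_moisture == pytest.approx(4.0 - 1.0, rel=1e-6)

    def test_direction_mismatch_warns(self):
        with pytest.warns(FitQualityWarning):
            fit_peleg_moisture(self._series(4.0, 2.0, 1.0), "absorption")

    def test_requires_t0(self):
        with pytest.raises(InsufficientDataError):
            fit_peleg_moisture(
                self._series(4.0, 2.0, 1.0, times=(1.0, 3.0, 5.0)), "desorption")
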