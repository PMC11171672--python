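"""Fick-slab diffusivity and Arrhenius activation energy."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from osmokin import (
    MoistureSeries,
    estimate_deff,
    fit_arrhenius,
    predict_mr,
    two_point_activation_energy,
)
from osmokin.diffusivity import (
    GAS_CONSTANT,
    NonphysicalDiffusivityError,
    SECONDS_PER_HOUR,
)
from osmokin.mass_transfer import InsufficientDataError
from osmokin.synthetic import generate_drying_family


def _series_from_mr(deff, L, times_h, M0=4.0, Me=0.2):
    pts = tuple(
        (t, Me + predict_mr(deff, L, t * SECONDS_PER_HOUR) * (M0 - Me))
        for t in times_h)
    return MoistureSeries("v", 20.0, pts, M0=M0, Me=Me)


class TestPredictMR:
    def test_time_zero_is_first_term_constant(self):
        assert predict_mr(1e-10, 0.0025, 0.0) == pytest.approx(8 / math.pi**2, rel=1e-12)

    def test_closed_form_value(self):
        deff, L, t = 3e-8, 0.025, 18000.0
        expected = (8 / math.pi**2) * math.exp(-math.pi**2 * deff * t / (4 * L**2))
        assert predict_mr(deff, L, t) == pytest.approx(expected, rel=1e-14)

    def test_log_linearity_in_deff(self):
        t, L = 3600.0, 0.0025
        gap1 = math.log(predict_mr(1e-10, L, t)) - math.log(8 / math.pi**2)
        gap2 = math.log(predict_mr(2e-10, L, t)) - math.log(8 / math.pi**2)
        assert gap2 == pytest.approx(2 * gap1, rel=1e-9)

    def test_strictly_decreasing(self):
        t = np.linspace(0, 5 * 3600, 200)
        y = predict_mr(2.92e-10, 0.0025, t)
        assert np.all(np.diff(y) < 0)


class TestEstimateDeff:
    @pytest.mark.parametrize("deff", [2.92e-10, 4.83e-10, 1e-9])
    def test_inverts_predict_mr(self, deff):
        """Generator-oracle identity: slope regression recovers Deff exactly."""
        fit = estimate_deff(_series_from_mr(deff, 0.0025, (1.0, 2.0, 3.0, 5.0)), 0.0025)
        assert fit.Deff == pytest.approx(deff, rel=1e-9)
        assert fit.intercept == pytest.approx(math.log(8 / math.pi**2), abs=1e-9)

    def test_two_point_exact(self):
        fit = estimate_deff(_series_from_mr(3e-10, 0.0025, (1.0, 4.0)), 0.0025)
        assert fit.Deff == pytest.approx(3e-10, rel=1e-9)

    def test_t0_point_excluded_as_mr_one(self):
        fit = estimate_deff(_series_from_mr(3e-10, 0.0025, (0.0, 1.0, 3.0, 5.0)), 0.0025)
        # MR(0) = 8/pi^2 < 1 so t=0 is usable under the first-term model
        assert fit.n_excluded == 0
        assert fit.Deff == pytest.approx(3e-10, rel=1e-9)

    def test_no_drying_signal(self):
        pts = ((1.0, 4.0), (3.0, 4.0), (5.0, 4.0))  # M == M0: MR == 1 throughout
        with pytest.raises(InsufficientDataError):
            estimate_deff(MoistureSeries("v", 20.0, pts, M0=4.0, Me=0.2), 0.0025)

    def test_rising_moisture_nonphysical(self):
        pts = ((1.0, 2.0), (3.0, 2.5), (5.0, 3.0))
        with pytest.raises(NonphysicalDiffusivityError):
            estimate_deff(MoistureSeries("v", 20.0, pts, M0=4.0, Me=0.2), 0.0025)


class TestArrhenius:
    def test_flat_deff_zero_activation(self):
        fit = fit_arrhenius([(20.0, 3e-10), (35.0, 3e-10), (50.0, 3e-10)])
        assert fit.Ea == pytest.approx(0.0, abs=1e-12)

    def test_two_point_closed_form_agreement(self):
        pts = [(20.0, 2.92e-10), (50.0, 4.83e-10)]
        fit = fit_arrhenius(pts)
        closed = two_point_activation_energy(20.0, 2.92e-10, 50.0, 4.83e-10)
        assert fit.Ea == pytest.approx(closed, rel=1e-10)
        assert closed == pytest.approx(13.2, abs=0.1)

    def test_two_point_symmetry(self):
        a = two_point_activation_energy(20.0, 3.55e-10, 50.0, 4.68e-10)
        b = two_point_activation_energy(50.0, 4.68e-10, 20.0, 3.55e-10)
        assert a == pytest.approx(b, rel=1e-12)
        assert a == pytest.approx(7.25, abs=0.05)

    def test_equal_temperature_rejected(self):
        with pytest.raises(ValueError):
            two_point_activation_energy(20.0, 1e-10, 20.0, 2e-10)
        with pytest.raises(InsufficientDataError):
            fit_arrhenius([(20.0, 1e-10), (20.0, 2e-10)])

    def test_synthetic_triple_recovery(self):
        D0, Ea = 1e-6, 12.0
        pairs = [
            (T, D0 * math.exp(-Ea * 1000 / (GAS_CONSTANT * (T + 273.15))))
            for T in (20.0, 35.0, 50.0)]
        fit = fit_arrhenius(pairs)
        assert fit.Ea == pytest.approx(Ea, rel=1e-6)
        assert fit.D0 == pytest.approx(D0, rel=1e-6)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    @given(factor=st.floats(0.1, 10.0))
    @settings(max_examples=50, deadline=None)
    def test_common_factor_leaves_ea_invariant(self, factor):
        pairs = [(20.0, 2.92e-10), (35.0, 3.8e-10), (50.0, 4.83e-10)]
        base = fit_arrhenius(pairs)
        scaled = fit_arrhenius([(T, factor * d) for T, d in pairs])
        assert scaled.Ea == pytest.approx(base.Ea, rel=1e-9)
        assert scaled.D0 == pytest.approx(factor * base.D0, rel=1e-9)


def test_drying_family_round_trip():
    """generate -> estimate -> fit recovers (D0, Ea) at zero noise."""
    D0, Ea = 5.7e-8, 12.873
    fam = generate_drying_family((D0, Ea), (20.0, 35.0, 50.0),
                                 (0.0, 1.0, 3.0, 5.0), L=0.0025,
                                 noise_logsd=0.0, seed=1)
    deffs = [(m.temperature, estimate_deff(m, 0.0025).Deff) for m in fam]
    fit = fit_arrhenius(deffs)
    assert fit.Ea == pytest.approx(Ea, rel=1e-6)
    assert fit.D0 == pytest.approx(D0, rel=1e-6)


def test_ea_recovery_under_lognormal_noise():
    """Median |Ea error| < 10% over seeded noisy replicates (2% log-noise)."""
    D0, Ea = 5.7e-8, 12.873
    errs = []
    for s in range(500):
        fam = generate_drying_family((D0, Ea), (20.0, 35.0, 50.0),
                                     (0.0, 1.0, 3.0, 5.0), L=0.0025,
                                     noise_logsd=0.02, seed=3000 + s)
        deffs = [(m.temperature, estimate_deff(m, 0.0025).Deff) for m in fam]
        errs.append(abs(fit_arrhenius(deffs).Ea - Ea) / Ea)
    assert np.median(errs) < 0.10
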