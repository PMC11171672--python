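"""Effective moisture diffusivity and Arrhenius activation energy.

The drying curve is reduced to the moisture ratio MR = (M - Me)/(M0 - Me) and
modelled by the first term of the analytic series solution of Fick's second
law for an infinite slab of half-thickness L (m) dried from both faces:

    MR(t) = (8 / pi^2) * exp(-pi^2 * Deff * t / (4 L^2)),   t in seconds.

ln MR is linear in t, so Deff (m^2/s) comes from an ordinary least-squares
slope: Deff = -slope * 4 L^2 / pi^2.  The intercept is reported against its
theoretical value ln(8/pi^2) as a model-adequacy diagnostic.

Across temperatures, Deff follows an Arrhenius law

    ln Deff = ln D0 - Ea / (R * (T + 273.15))

with R = 8.314 J/(mol K); the activation energy Ea (reported in kJ/mol) is
-slope * R of the ln Deff vs 1/T_abs regression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .mass_transfer import (
    DegenerateSeriesError,
    InsufficientDataError,
    compute_moisture_ratio,
)

__all__ = [
    "MoistureSeries",
    "DiffusivityFit",
    "ArrheniusFit",
    "NonphysicalDiffusivityError",
    "predict_mr",
    "estimate_deff",
    "fit_arrhenius",
    "two_point_activation_energy",
    "GAS_CONSTANT",
    "SECONDS_PER_HOUR",
]

GAS_CONSTANT = 8.314          # J/(mol K)
SECONDS_PER_HOUR = 3600.0
_LN_8_PI2 = math.log(8.0 / math.pi**2)


class NonphysicalDiffusivityError(ValueError):
    """The ln(MR) slope is non-negative: moisture is not decreasing."""


@dataclass(frozen=True)
class MoistureSeries:
    """Dry-basis moisture curve at one variety x temperature.

    ``points`` are (time in hours, moisture in kg water / kg dry matter);
    ``M0`` and ``Me`` are the initial and equilibrium moisture contents used
    for the moisture-ratio reduction.
    """

    variety: str
    temperature: float          # degrees Celsius
    points: tuple[tuple[float, float], ...]
    M0: float
    Me: float

    def __post_init__(self) -> None:
        if not (self.M0 > self.Me >= 0):
            raise DegenerateSeriesError(
                f"drying requires M0 > Me >= 0, got M0={self.M0}, Me={self.Me}")
        times = [t for t, _ in self.points]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("point times must be strictly increasing")

    @property
    def Xw0(self) -> float:
        """Initial dry-basis moisture (alias of M0)."""
        return self.M0


@dataclass(frozen=True)
class DiffusivityFit:
    """Per-temperature effective diffusivity from the ln(MR) regression."""

    Deff: float        # m^2/s
    L: float           # slab half-thickness, m
    slope: float       # 1/s
    intercept: float   # dimensionless; compare to ln(8/pi^2) ~ -0.2100
    r2: float
    n_points: int
    n_excluded: int    # points dropped because MR <= 0 or >= 1
    temperature: float

    def __post_init__(self) -> None:
        if not (self.Deff > 0 and self.L > 0):
            raise ValueError(f"Deff and L must be positive: {self.Deff}, {self.L}")

    @property
    def intercept_theory(self) -> float:
        return _LN_8_PI2


@dataclass(frozen=True)
class ArrheniusFit:
    """Cross-temperature Arrhenius parameters for Deff."""

    D0: float            # m^2/s
    Ea: float            # kJ/mol
    Ea_sd: float         # kJ/mol
    Ea_ci95: tuple[float, float]
    r2: float
    n_points: int
    variety: Optional[str] = None
    gas_constant: float = GAS_CONSTANT   # J/(mol K), fixed

    def __post_init__(self) -> None:
        if not self.D0 > 0:
            raise ValueError(f"D0 must be positive, got {self.D0}")


def predict_mr(Deff: float, L: float, t) -> np.ndarray | float:
    """First-term slab moisture ratio at time ``t`` (seconds)."""
    if not (Deff > 0 and L > 0):
        raise ValueError("Deff and L must be positive")
    ts = np.asarray(t, dtype=float)
    if np.any(ts < 0):
        raise ValueError("time must be non-negative")
    out = (8.0 / math.pi**2) * np.exp(-(math.pi**2) * Deff * ts / (4.0 * L**2))
    return float(out) if np.isscalar(t) or ts.ndim == 0 else out


def estimate_deff(series: MoistureSeries, L: float) -> DiffusivityFit:
    """Effective diffusivity from the ln(MR) vs time OLS slope.

    Times are hours at the interface and converted to seconds internally, so
    Deff comes out in m^2/s.  Points with MR outside (0, 1) are excluded
    (their count is reported on the fit).
    """
    if not L > 0:
        raise ValueError(f"half-thickness L must be positive, got {L}")
    t_h = np.array([t for t, _ in series.points], dtype=float)
    M = np.array([m for _, m in series.points], dtype=float)
    mr = np.array([compute_moisture_ratio(m, series.M0, series.Me) for m in M])

    usable = (mr > 0) & (mr < 1)
    n_excluded = int((~usable).sum())
    if usable.sum() < 2:
        raise InsufficientDataError(
            f"need >= 2 points with 0 < MR < 1, got {int(usable.sum())}")

    t_s = t_h[usable] * SECONDS_PER_HOUR
    y = np.log(mr[usable])
    A = np.column_stack([np.ones(t_s.size), t_s])
    (intercept, slope), *_ = np.linalg.lstsq(A, y, rcond=None)
    if slope >= 0:
        raise NonphysicalDiffusivityError(
            f"ln(MR) slope {slope:.3g} >= 0: moisture ratio is not decreasing")

    resid = y - A @ (intercept, slope)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / sst if sst > 0 else 1.0

    deff = -float(slope) * 4.0 * L**2 / math.pi**2
    return DiffusivityFit(
        Deff=deff, L=L, slope=float(slope), intercept=float(intercept),
        r2=r2, n_points=int(usable.sum()), n_excluded=n_excluded,
        temperature=series.temperature,
    )


def fit_arrhenius(deffs: Sequence[tuple[float, float]],
                  ci_level: float = 0.95,
                  variety: Optional[str] = None) -> ArrheniusFit:
    """Arrhenius regression of ln(Deff) on reciprocal absolute temperature.

    ``deffs`` is a sequence of (temperature degC, Deff m^2/s) pairs at >= 2
    distinct temperatures.  Ea = -slope * R, in kJ/mol; its SD and CI follow
    from the slope's standard error (t-quantile, df = N - 2; NaN at N = 2).
    """
    temps = np.array([T for T, _ in deffs], dtype=float)
    ds = np.array([d for _, d in deffs], dtype=float)
    if np.unique(temps).size < 2:
        raise InsufficientDataError("need >= 2 distinct temperatures")
    if np.any(ds <= 0):
        raise ValueError("all Deff must be positive")

    xr = 1.0 / (temps + 273.15)
    y = np.log(ds)
    A = np.column_stack([np.ones(xr.size), xr])
    (intercept, slope), *_ = np.linalg.lstsq(A, y, rcond=None)

    resid = y - A @ (intercept, slope)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / sst if sst > 0 else 1.0

    N = xr.size
    df = N - 2
    if df > 0:
        sigma2 = float(np.sum(resid**2)) / df
        sxx = float(np.sum((xr - xr.mean()) ** 2))
        slope_se = math.sqrt(sigma2 / sxx)
        tq = stats.t.ppf(0.5 + ci_level / 2.0, df)
    else:
        slope_se = float("nan")
        tq = float("nan")

    ea_kj = -float(slope) * GAS_CONSTANT / 1000.0
    ea_sd = slope_se * GAS_CONSTANT / 1000.0
    return ArrheniusFit(
        D0=float(np.exp(intercept)), Ea=ea_kj, Ea_sd=ea_sd,
        Ea_ci95=(ea_kj - tq * ea_sd, ea_kj + tq * ea_sd),
        r2=r2, n_points=N, variety=variety,
    )


def two_point_activation_energy(T1: float, D1: float, T2: float, D2: float) -> float:
    """Closed-form activation energy (kJ/mol) from two (degC, m^2/s) points.

    Ea = R * ln(D2/D1) / (1/T1_abs - 1/T2_abs); symmetric under swapping the
    points and exactly equal to :func:`fit_arrhenius` on the same pair.
    """
    if T1 == T2:
        raise ValueError("temperatures must differ")
    if not (D1 > 0 and D2 > 0):
        raise ValueError("diffusivities must be positive")
    inv1 = 1.0 / (T1 + 273.15)
    inv2 = 1.0 / (T2 + 273.15)
    return GAS_CONSTANT * math.log(D2 / D1) / (inv1 - inv2) / 1000.0
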