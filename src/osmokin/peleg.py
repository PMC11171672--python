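"""Modified Peleg sorption kinetics for water loss and solid gain.

The two-parameter Peleg model describes the hyperbolic approach of a sorption
response Y(t) (water loss WL or solid gain SG, g per g initial sample) to its
equilibrium value:

    Y(t) = t / (k1 + k2 * t)

where k1 (h.g/g) is the rate constant and k2 (g/g) the capacity constant.  Two
derived quantities follow exactly from the constants:

    initial rate  dY/dt |_{t->0} = 1 / k1
    equilibrium   Y_inf          = 1 / k2

The original moisture form X_w(t) = X_w0 +/- t/(k1 + k2 t) covers absorption
(plus sign) and desorption (minus sign) of dry-basis moisture.

Fitting is bounded nonlinear least squares over the positive orthant, started
from the linearised form t/Y = k1 + k2 t and hardened by a deterministic
multiplicative restart schedule.  The model passes through the origin
identically, so zero-time anchor points constrain nothing: they are excluded
from the regression and from the residual degrees of freedom (df = N - 2 with
N the number of positive-time points), which is what makes the reported
asymptotic confidence intervals honest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy import optimize, stats

from .mass_transfer import DegenerateSeriesError, InsufficientDataError, KineticSeries
from .metrics import FitDiagnostics, compute_diagnostics

__all__ = [
    "PelegFit",
    "FitFailureError",
    "InvalidFitError",
    "FitQualityWarning",
    "fit_peleg",
    "fit_peleg_moisture",
    "predict_peleg",
    "peleg_initial_rate",
    "peleg_equilibrium",
]

#: multiplicative perturbations applied to the base start (deterministic order)
RESTART_FACTORS: tuple[tuple[float, float], ...] = (
    (1.0, 1.0),
    (0.25, 1.0), (0.5, 1.0), (2.0, 1.0), (4.0, 1.0),
    (1.0, 0.25), (1.0, 0.5), (1.0, 2.0), (1.0, 4.0),
    (0.25, 0.25), (4.0, 4.0),
)


class FitFailureError(RuntimeError):
    """No restart converged; carries the best incumbent parameters."""

    def __init__(self, message: str, incumbent=None):
        super().__init__(message)
        self.incumbent = incumbent


class InvalidFitError(ValueError):
    """Fit parameters violate their positivity constraints."""


class FitQualityWarning(UserWarning):
    """The fitted model is suspect (sign mismatch, boundary solution, ...)."""


@dataclass(frozen=True)
class PelegFit:
    """Fitted Peleg constants with asymptotic uncertainty.

    ``initial_rate`` and ``equilibrium`` are properties recomputed from the
    constants, never stored, so the reparameterisation identities
    ``initial_rate * k1 == 1`` and ``equilibrium * k2 == 1`` hold exactly.
    """

    kind: str                 # "WL", "SG" or "moisture"
    k1: float                 # h.g/g
    k2: float                 # g/g
    k1_sd: float
    k2_sd: float
    k1_ci95: tuple[float, float]
    k2_ci95: tuple[float, float]
    n_points: int             # positive-time points used in the regression
    diagnostics: Optional[FitDiagnostics] = None
    variety: Optional[str] = None
    temperature: Optional[float] = None
    xw0: Optional[float] = None        # moisture form only
    direction: Optional[str] = None    # "absorption" | "desorption"

    def __post_init__(self) -> None:
        if not (self.k1 > 0 and self.k2 > 0):
            raise InvalidFitError(
                f"Peleg constants must be positive: k1={self.k1}, k2={self.k2}")

    @property
    def initial_rate(self) -> float:
        """Initial sorption rate 1/k1 (g/g per hour)."""
        return 1.0 / self.k1

    @property
    def equilibrium(self) -> float:
        """Equilibrium response 1/k2 (g/g): WL_inf or SG_inf."""
        return 1.0 / self.k2

    @property
    def equilibrium_moisture(self) -> Optional[float]:
        """X_w0 -/+ 1/k2 for moisture-form fits, None otherwise."""
        if self.xw0 is None or self.direction is None:
            return None
        sign = 1.0 if self.direction == "absorption" else -1.0
        return self.xw0 + sign / self.k2

    @classmethod
    def from_constants(cls, k1: float, k2: float, kind: str = "WL") -> "PelegFit":
        """Build a fit object from externally reported constants (no data)."""
        return cls(kind=kind, k1=k1, k2=k2,
                   k1_sd=float("nan"), k2_sd=float("nan"),
                   k1_ci95=(float("nan"), float("nan")),
                   k2_ci95=(float("nan"), float("nan")),
                   n_points=0)


def _curve(t: np.ndarray, k1: float, k2: float) -> np.ndarray:
    return t / (k1 + k2 * t)


def predict_peleg(fit: PelegFit, t) -> np.ndarray | float:
    """Evaluate Y(t) = t / (k1 + k2 t); monotone, concave, bounded by 1/k2."""
    ts = np.asarray(t, dtype=float)
    if np.any(ts < 0):
        raise ValueError("time must be non-negative")
    out = _curve(ts, fit.k1, fit.k2)
    return float(out) if np.isscalar(t) or ts.ndim == 0 else out


def peleg_initial_rate(fit: PelegFit) -> float:
    """Initial dehydration/sorption rate 1/k1 (g/g per hour)."""
    if not fit.k1 > 0:
        raise InvalidFitError(f"k1 must be positive, got {fit.k1}")
    return 1.0 / fit.k1


def peleg_equilibrium(fit: PelegFit) -> float:
    """Equilibrium WL/SG estimate 1/k2 (g/g)."""
    if not fit.k2 > 0:
        raise InvalidFitError(f"k2 must be positive, got {fit.k2}")
    return 1.0 / fit.k2


def _linearized_start(t: np.ndarray, Y: np.ndarray) -> tuple[float, float]:
    """OLS on t/Y = k1 + k2 t over strictly positive responses."""
    pos = Y > 0
    if pos.sum() >= 2:
        z = t[pos] / Y[pos]
        A = np.column_stack([np.ones(pos.sum()), t[pos]])
        (k1, k2), *_ = np.linalg.lstsq(A, z, rcond=None)
        if k1 > 0 and k2 > 0:
            return float(k1), float(k2)
    # fallback when the linearisation is unusable
    ymax = float(np.max(Y)) if np.max(Y) > 0 else 1.0
    return 1.0, 1.0 / ymax


def _fit_core(t: np.ndarray, Y: np.ndarray, ci_level: float):
    """Bounded least squares with the restart schedule; returns params + inference."""

    def resid(theta: np.ndarray) -> np.ndarray:
        return Y - _curve(t, theta[0], theta[1])

    base = np.array(_linearized_start(t, Y))
    best = None
    for f1, f2 in RESTART_FACTORS:
        start = np.clip(base * (f1, f2), 1e-10, 1e8)
        sol = optimize.least_squares(
            resid, start, bounds=(1e-12, np.inf), method="trf",
            xtol=1e-14, ftol=1e-14, gtol=1e-14)
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success:
        raise FitFailureError(
            "Peleg fit did not converge under the restart schedule",
            incumbent=None if best is None else tuple(best.x))

    k1, k2 = (float(v) for v in best.x)
    sse = float(2.0 * best.cost)
    N = t.size
    df = N - 2
    if df > 0:
        sigma2 = sse / df
        JtJ = best.jac.T @ best.jac
        try:
            cov = sigma2 * np.linalg.inv(JtJ)
            sds = np.sqrt(np.diag(cov))
        except np.linalg.LinAlgError:
            sds = np.full(2, np.nan)
        tq = stats.t.ppf(0.5 + ci_level / 2.0, df)
    else:
        sds = np.full(2, np.nan)
        tq = np.nan
    k1_sd, k2_sd = (float(s) for s in sds)
    return (k1, k2, k1_sd, k2_sd,
            (k1 - tq * k1_sd, k1 + tq * k1_sd),
            (k2 - tq * k2_sd, k2 + tq * k2_sd),
            N)


def _series_diagnostics(series: KineticSeries, k1: float, k2: float,
                        xw0: float = 0.0, sign: float = 1.0) -> FitDiagnostics:
    """Error battery over the full series (anchor included).

    SSE/RMSE/chi2/r2 use every point; the relative-deviation metrics
    (MPE/AARD) are taken over nonzero experimental responses only, since the
    structural zero anchor makes the relative deviation 0/0.
    """
    Y = series.Y
    pred = xw0 + sign * _curve(series.t, k1, k2)
    full = compute_diagnostics(Y, pred, n_params=2) if np.all(Y != 0) else None
    if full is not None:
        return full
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = compute_diagnostics(Y, pred, n_params=2)
    nz = Y != 0
    if nz.sum() > 2:
        sub = compute_diagnostics(Y[nz], pred[nz], n_params=2)
        full = replace(full, mpe=sub.mpe, aard=sub.aard)
    return full


def fit_peleg(series: KineticSeries, ci_level: float = 0.95) -> PelegFit:
    """Fit the modified Peleg model to a WL or SG kinetic series.

    Minimises the sum of squared residuals over (k1, k2) > 0.  Parameter SDs
    come from the asymptotic (Jacobian) covariance; confidence intervals use
    the t-distribution with df = N - 2, N counting positive-time points.
    """
    if series.kind == "moisture":
        raise ValueError("use fit_peleg_moisture for moisture-form series")
    t_all, Y_all = series.t, series.Y
    if series.kind in ("WL", "SG") and not np.any((t_all == 0) & (Y_all == 0)):
        raise InsufficientDataError("WL/SG series must include the (0, 0) anchor")
    if np.all(Y_all[t_all > 0] == 0):
        raise DegenerateSeriesError("response is identically zero: no signal to fit")
    if np.any(Y_all[t_all > 0] < 0):
        warnings.warn("negative responses at t > 0; fit proceeds unclipped",
                      FitQualityWarning, stacklevel=2)

    mask = t_all > 0
    t, Y = t_all[mask], Y_all[mask]
    if t.size < 2:
        raise InsufficientDataError(
            f"need >= 2 positive-time points, got {t.size}")

    k1, k2, k1_sd, k2_sd, ci1, ci2, N = _fit_core(t, Y, ci_level)
    diag = _series_diagnostics(series, k1, k2)
    return PelegFit(kind=series.kind, k1=k1, k2=k2,
                    k1_sd=k1_sd, k2_sd=k2_sd, k1_ci95=ci1, k2_ci95=ci2,
                    n_points=N, diagnostics=diag,
                    variety=series.variety, temperature=series.temperature)


def fit_peleg_moisture(series: KineticSeries, direction: str,
                       ci_level: float = 0.95) -> PelegFit:
    """Fit the moisture form X_w(t) = X_w0 +/- t/(k1 + k2 t).

    ``direction`` fixes the sign: "absorption" adds, "desorption" subtracts.
    X_w0 is taken from the t = 0 point, which must be present.
    """
    if series.kind != "moisture":
        raise ValueError(f"series kind must be 'moisture', got {series.kind!r}")
    if direction not in ("absorption", "desorption"):
        raise ValueError(f"direction must be absorption/desorption, got {direction!r}")
    t_all, X = series.t, series.Y
    if t_all[0] != 0:
        raise InsufficientDataError("moisture series must start at t = 0 (X_w0)")
    xw0 = float(X[0])
    sign = 1.0 if direction == "absorption" else -1.0

    Y_all = sign * (X - xw0)
    mask = t_all > 0
    t, Y = t_all[mask], Y_all[mask]
    if t.size < 2:
        raise InsufficientDataError(f"need >= 2 positive-time points, got {t.size}")
    if np.all(Y == 0):
        raise DegenerateSeriesError("moisture never departs from X_w0")
    if np.sum(Y) < 0:
        warnings.warn(
            f"data trend contradicts direction={direction!r}; fit is suspect",
            FitQualityWarning, stacklevel=2)

    k1, k2, k1_sd, k2_sd, ci1, ci2, N = _fit_core(t, Y, ci_level)
    diag = _series_diagnostics(series, k1, k2, xw0=xw0, sign=sign)
    return PelegFit(kind="moisture", k1=k1, k2=k2,
                    k1_sd=k1_sd, k2_sd=k2_sd, k1_ci95=ci1, k2_ci95=ci2,
                    n_points=N, diagnostics=diag,
                    variety=series.variety, temperature=series.temperature,
                    xw0=xw0, direction=direction)
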