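"""GAB (Guggenheim-Anderson-de Boer) moisture sorption isotherm.

Relates equilibrium dry-basis moisture x (kg water / kg dry matter) to water
activity a_w through three parameters:

    x(a_w) = Xm * C * K * a_w / [(1 - K a_w) * (1 - K a_w + C K a_w)]

Xm is the monolayer moisture content (kg/kg), C the Guggenheim energy
constant, K the multilayer correction factor.  K = 1 collapses the model to
the BET isotherm.  The curve is strictly increasing in a_w and diverges as
K a_w -> 1, so fitted K is bounded strictly below 1/max(a_w).

Fitting minimises unweighted SSE in x under box bounds, inside a seeded
Latin-hypercube multistart; the fit is declared stable when the two best
restarts agree to 1e-6 relative in every parameter.  Identical inputs and
seed give bit-identical results.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats
from scipy.stats import qmc

from .mass_transfer import InsufficientDataError
from .metrics import FitDiagnostics, compute_diagnostics
from .peleg import FitFailureError, FitQualityWarning

__all__ = [
    "IsothermPoint",
    "GABFit",
    "predict_gab",
    "fit_gab",
    "invert_gab",
    "GAB_BOUNDS",
]

#: box bounds for (Xm, C); the K upper bound is data-dependent
GAB_BOUNDS = {"Xm": (1e-6, 1.0), "C": (1e-6, 1e3), "K": (1e-6, 0.9999)}

#: relative agreement between the two best restarts that declares stability
STABILITY_RTOL = 1e-6


@dataclass(frozen=True)
class IsothermPoint:
    """One (water activity, equilibrium moisture) observation."""

    aw: float  # dimensionless, in (0, 1)
    x: float   # kg water / kg dry matter

    def __post_init__(self) -> None:
        if not (0 < self.aw < 1):
            raise ValueError(f"aw must lie in (0, 1), got {self.aw}")
        if self.x < 0:
            raise ValueError(f"moisture must be non-negative, got {self.x}")


@dataclass(frozen=True)
class GABFit:
    """Fitted GAB parameters with restart metadata and asymptotic uncertainty."""

    Xm: float
    C: float
    K: float
    Xm_sd: float
    C_sd: float
    K_sd: float
    Xm_ci95: tuple[float, float]
    C_ci95: tuple[float, float]
    K_ci95: tuple[float, float]
    sse: float
    n_restarts_used: int
    stable: bool
    max_aw: float
    diagnostics: Optional[FitDiagnostics] = None
    variety: Optional[str] = None
    temperature: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.Xm > 0 and self.C > 0 and self.K > 0):
            raise ValueError(
                f"GAB parameters must be positive: Xm={self.Xm}, C={self.C}, K={self.K}")
        if self.K * self.max_aw >= 1:
            raise ValueError(
                f"K*max(aw) = {self.K * self.max_aw:.6g} >= 1: isotherm diverges on data")

    @property
    def ck_product(self) -> float:
        """The product C*K, reported alongside C and K (see package docs)."""
        return self.C * self.K

    @classmethod
    def from_parameters(cls, Xm: float, C: float, K: float) -> "GABFit":
        """Build a fit object from externally supplied parameters (no data)."""
        nan2 = (float("nan"), float("nan"))
        return cls(Xm=Xm, C=C, K=K,
                   Xm_sd=float("nan"), C_sd=float("nan"), K_sd=float("nan"),
                   Xm_ci95=nan2, C_ci95=nan2, K_ci95=nan2,
                   sse=float("nan"), n_restarts_used=0, stable=True, max_aw=0.0)


def _gab(aw: np.ndarray, Xm: float, C: float, K: float) -> np.ndarray:
    kaw = K * aw
    return Xm * C * kaw / ((1.0 - kaw) * (1.0 - kaw + C * kaw))


def _gab_grad(aw: np.ndarray, Xm: float, C: float, K: float) -> np.ndarray:
    """Analytic gradient of the isotherm wrt (Xm, C, K), shape (len(aw), 3)."""
    s = C * K * aw            # sorbed-layer term
    d1 = 1.0 - K * aw
    d2 = d1 + s
    f = Xm * s / (d1 * d2)
    df_ds = Xm / d2**2        # d f / d s at fixed d1 cancels to this
    d_dC = df_ds * K * aw
    # K enters s, d1 and d2
    ds = C * aw
    dd1 = -aw
    dd2 = aw * (C - 1.0)
    d_dK = Xm * (ds * d1 * d2 - s * (dd1 * d2 + d1 * dd2)) / (d1 * d2) ** 2
    return np.column_stack([f / Xm, d_dC, d_dK])


def predict_gab(fit: GABFit, aw) -> np.ndarray | float:
    """Evaluate the isotherm at ``aw``; requires K*aw < 1."""
    a = np.asarray(aw, dtype=float)
    if np.any(a < 0):
        raise ValueError("aw must be non-negative")
    if np.any(fit.K * a >= 1):
        raise ValueError(f"K*aw >= 1: isotherm diverges (K = {fit.K:.6g})")
    out = _gab(a, fit.Xm, fit.C, fit.K)
    return float(out) if np.isscalar(aw) or a.ndim == 0 else out


def _restart_starts(n_restarts: int, seed: int, bounds_lo: np.ndarray,
                    bounds_hi: np.ndarray, x_data: np.ndarray) -> np.ndarray:
    """Heuristic start plus a seeded Latin-hypercube over the bounds.

    C spans nine decades, so its LHS coordinate is sampled log-uniformly;
    Xm and K are sampled uniformly.
    """
    heuristic = np.array([
        np.clip(0.25 * float(np.max(x_data)), bounds_lo[0], bounds_hi[0]),
        10.0,
        np.clip(0.9 * bounds_hi[2], bounds_lo[2], bounds_hi[2]),
    ])
    if n_restarts <= 1:
        return heuristic[None, :]
    sampler = qmc.LatinHypercube(d=3, seed=seed)
    unit = sampler.random(n_restarts - 1)
    starts = np.empty_like(unit)
    starts[:, 0] = bounds_lo[0] + unit[:, 0] * (bounds_hi[0] - bounds_lo[0])
    lc = np.log10(bounds_lo[1]), np.log10(bounds_hi[1])
    starts[:, 1] = 10.0 ** (lc[0] + unit[:, 1] * (lc[1] - lc[0]))
    starts[:, 2] = bounds_lo[2] + unit[:, 2] * (bounds_hi[2] - bounds_lo[2])
    return np.vstack([heuristic, starts])


def fit_gab(points: Sequence[IsothermPoint], n_restarts: int = 32,
            seed: int = 0, ci_level: float = 0.95,
            variety: Optional[str] = None,
            temperature: Optional[float] = None) -> GABFit:
    """Fit (Xm, C, K) by bounded multi-restart SSE minimisation.

    Deterministic for fixed (points, n_restarts, seed).  Raises
    :class:`FitFailureError` (carrying the best incumbent) if no restart
    converges; flags boundary/degenerate solutions with a warning.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    aw = np.array([p.aw for p in points], dtype=float)
    x = np.array([p.x for p in points], dtype=float)
    if np.unique(aw).size < 3:
        raise InsufficientDataError(
            f"need >= 3 points with distinct aw, got {np.unique(aw).size}")

    max_aw = float(np.max(aw))
    k_hi = min(GAB_BOUNDS["K"][1], 0.9999 / max_aw)
    lo = np.array([GAB_BOUNDS["Xm"][0], GAB_BOUNDS["C"][0], GAB_BOUNDS["K"][0]])
    hi = np.array([GAB_BOUNDS["Xm"][1], GAB_BOUNDS["C"][1], k_hi])

    def resid(theta: np.ndarray) -> np.ndarray:
        return x - _gab(aw, *theta)

    def jac(theta: np.ndarray) -> np.ndarray:
        return -_gab_grad(aw, *theta)

    solutions = []
    for start in _restart_starts(n_restarts, seed, lo, hi, x):
        sol = optimize.least_squares(
            resid, np.clip(start, lo * (1 + 1e-12), hi * (1 - 1e-12)),
            jac=jac, bounds=(lo, hi), method="trf",
            xtol=1e-10, ftol=1e-10, gtol=1e-10, max_nfev=120)
        if sol.success:
            solutions.append(sol)
    if not solutions:
        raise FitFailureError("no GAB restart converged", incumbent=None)

    solutions.sort(key=lambda s: s.cost)
    # polish the incumbent to full precision
    best = optimize.least_squares(
        resid, solutions[0].x, jac=jac, bounds=(lo, hi), method="trf",
        xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=500)
    if best.cost > solutions[0].cost:
        best = solutions[0]
    stable = False
    if len(solutions) >= 2:
        a, b = solutions[0].x, solutions[1].x
        stable = bool(np.all(np.abs(a - b) <= STABILITY_RTOL * np.abs(a)))

    theta = best.x.copy()
    if np.any(np.isclose(theta, lo, rtol=1e-6)) or np.any(np.isclose(theta, hi, rtol=1e-6)):
        warnings.warn("GAB solution sits on a parameter bound; treat with caution",
                      FitQualityWarning, stacklevel=2)

    Xm, C, K = (float(v) for v in theta)
    sse = float(2.0 * best.cost)
    N = aw.size
    df = N - 3
    if df > 0:
        sigma2 = sse / df
        try:
            cov = sigma2 * np.linalg.inv(best.jac.T @ best.jac)
            sds = np.sqrt(np.diag(cov))
        except np.linalg.LinAlgError:
            sds = np.full(3, np.nan)
        tq = stats.t.ppf(0.5 + ci_level / 2.0, df)
    else:
        sds = np.full(3, np.nan)
        tq = np.nan

    diag = None
    if N > 3:
        diag = compute_diagnostics(x, _gab(aw, Xm, C, K), n_params=3)

    cis = [(float(v - tq * s), float(v + tq * s)) for v, s in zip(theta, sds)]
    return GABFit(
        Xm=Xm, C=C, K=K,
        Xm_sd=float(sds[0]), C_sd=float(sds[1]), K_sd=float(sds[2]),
        Xm_ci95=cis[0], C_ci95=cis[1], K_ci95=cis[2],
        sse=sse, n_restarts_used=len(solutions), stable=stable,
        max_aw=max_aw, diagnostics=diag,
        variety=variety, temperature=temperature,
    )


def invert_gab(fit: GABFit, x: float) -> float:
    """Water activity at which the isotherm attains moisture ``x``.

    Bracketed root-finding on (0, aw_max) where aw_max approaches
    min(1, 1/K); the round trip predict(invert(x)) = x holds to ~1e-10.
    """
    if not x > 0:
        raise ValueError(f"moisture must be positive, got {x}")
    aw_hi = min(1.0, 1.0 / fit.K) * (1.0 - 1e-9)
    x_hi = _gab(np.asarray(aw_hi), fit.Xm, fit.C, fit.K)
    if x >= x_hi:
        raise ValueError(
            f"moisture {x:.6g} outside attainable isotherm range (max {x_hi:.6g})")
    f = lambda a: _gab(np.asarray(a), fit.Xm, fit.C, fit.K) - x
    return float(optimize.brentq(f, 1e-15, aw_hi, xtol=1e-14, rtol=8.9e-16))
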