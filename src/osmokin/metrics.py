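"""Goodness-of-fit battery for dehydration/sorption model validation.

Seven metrics computed from an (experimental, predicted) vector pair with N
observations and n fitted constants:

    chi2 = SSE / (N - n)                 reduced chi-square
    RMSE = sqrt(SSE / N)
    MBE  = mean(x_pre - x_exp)           mean bias error
    MPE  = 100/N * sum|x_pre - x_exp| / x_exp   mean percentage error
    SSE  = sum (x_pre - x_exp)^2
    AARD = MPE / 100                     average absolute relative deviation
    r2   = 1 - SSE / SST                 coefficient of determination

MPE and AARD differ only by the factor 100; both are reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "FitDiagnostics",
    "compute_diagnostics",
    "UndefinedMetricWarning",
    "DegreesOfFreedomError",
]


class DegreesOfFreedomError(ValueError):
    """N <= n: reduced chi-square undefined."""


class UndefinedMetricWarning(UserWarning):
    """A metric is undefined for this input (zero experimental value or variance)."""


@dataclass(frozen=True)
class FitDiagnostics:
    """The seven-metric error battery for one fitted model.

    ``mpe``/``aard`` are NaN when some experimental value is zero; ``r2`` is
    NaN when the experimental vector is constant.  Undefined metrics are
    reported as NaN with a warning, never silently dropped.
    """

    chi2: float   # squared response units
    rmse: float   # response units
    mbe: float    # response units
    mpe: float    # percent
    sse: float    # squared response units
    aard: float   # dimensionless fraction
    r2: float
    N: int        # observations
    n: int        # fitted constants


def compute_diagnostics(x_exp, x_pre, n_params: int) -> FitDiagnostics:
    """Compute the full error battery for experimental vs predicted vectors."""
    xe = np.asarray(x_exp, dtype=float)
    xp = np.asarray(x_pre, dtype=float)
    if xe.shape != xp.shape or xe.ndim != 1:
        raise ValueError(f"shape mismatch: {xe.shape} vs {xp.shape} (need equal 1-D)")
    N = xe.size
    if N <= n_params:
        raise DegreesOfFreedomError(
            f"need N > n: got N={N}, n={n_params}")

    resid = xp - xe
    sse = float(np.sum(resid**2))
    rmse = float(np.sqrt(sse / N))
    mbe = float(np.mean(resid))
    chi2 = sse / (N - n_params)

    if np.any(xe == 0):
        warnings.warn(
            "experimental vector contains zeros: MPE/AARD undefined (NaN)",
            UndefinedMetricWarning, stacklevel=2)
        aard = float("nan")
        mpe = float("nan")
    else:
        aard = float(np.mean(np.abs(resid / xe)))
        mpe = 100.0 * aard

    sst = float(np.sum((xe - xe.mean()) ** 2))
    if sst == 0.0:
        if sse > 0:
            warnings.warn(
                "experimental vector is constant: r2 undefined (NaN)",
                UndefinedMetricWarning, stacklevel=2)
            r2 = float("nan")
        else:
            r2 = 1.0
    else:
        r2 = 1.0 - sse / sst

    return FitDiagnostics(
        chi2=chi2, rmse=rmse, mbe=mbe, mpe=mpe, sse=sse, aard=aard,
        r2=r2, N=N, n=n_params,
    )
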