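"""Mass-transfer quantities for osmotic dehydration.

Converts raw gravimetric measurements (sample weight, dry matter, water mass)
into the dimensionless quantities the kinetic models consume:

* solid gain    SG = (u - u0) / w0        (g solutes absorbed per g initial sample)
* water loss    WL = (ww0 - ww) / w0      (g water removed per g initial sample)
* moisture ratio MR = (M - Me) / (M0 - Me) (normalised dry-basis moisture, 1 -> 0)

and groups replicate measurements into per-condition kinetic series.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ODMeasurement",
    "KineticPoint",
    "KineticSeries",
    "InvalidMeasurementError",
    "GroupingError",
    "InsufficientDataError",
    "DegenerateSeriesError",
    "MassBalanceWarning",
    "NegativeTransferWarning",
    "compute_solid_gain",
    "compute_water_loss",
    "compute_moisture_ratio",
    "dry_basis_moisture",
    "build_kinetic_series",
    "read_measurements",
    "measurements_to_frame",
    "CSV_COLUMNS",
]

#: canonical long-format CSV header
CSV_COLUMNS = (
    "variety", "temperature_C", "time_h", "replicate",
    "w0_g", "u0_g", "u_g", "ww0_g", "ww_g", "aw",
)

#: relative tolerance on the wet-weight balance ww0 + u0 = w0 before a warning
MASS_BALANCE_RTOL = 1e-6

VALID_KINDS = ("WL", "SG", "moisture")


class InvalidMeasurementError(ValueError):
    """A raw measurement violates a hard physical invariant."""


class GroupingError(ValueError):
    """Measurements mixed across varieties or temperatures."""


class InsufficientDataError(ValueError):
    """Too few (time) points for the requested operation."""


class DegenerateSeriesError(ValueError):
    """Series carries no usable signal (e.g. M0 = Me, all-zero response)."""


class MassBalanceWarning(UserWarning):
    """ww0 + u0 deviates from w0 beyond the strict tolerance."""


class NegativeTransferWarning(UserWarning):
    """Measurement noise produced a negative WL or SG value."""


@dataclass(frozen=True)
class ODMeasurement:
    """One raw osmotic-dehydration observation.

    All masses in grams.  ``aw`` is the water activity measured on the treated
    sample (dimensionless, in (0, 1]); it may be absent.
    """

    variety: str
    temperature: float  # degrees Celsius
    time: float         # hours
    replicate: int
    w0: float   # initial sample weight
    u0: float   # initial dry matter
    u: float    # dry matter after treatment
    ww0: float  # initial water mass
    ww: float   # water mass at time t
    aw: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.w0 > 0):
            raise InvalidMeasurementError(f"w0 must be positive, got {self.w0}")
        if not (0 < self.u0 < self.w0):
            raise InvalidMeasurementError(
                f"u0 must satisfy 0 < u0 < w0, got u0={self.u0}, w0={self.w0}")
        if not (self.u > 0):
            raise InvalidMeasurementError(f"u must be positive, got {self.u}")
        if self.ww < 0:
            raise InvalidMeasurementError(f"ww must be non-negative, got {self.ww}")
        if self.time < 0:
            raise InvalidMeasurementError(f"time must be non-negative, got {self.time}")
        if self.replicate < 1:
            raise InvalidMeasurementError(
                f"replicate index must be >= 1, got {self.replicate}")
        if self.aw is not None and not (0 < self.aw <= 1):
            raise InvalidMeasurementError(f"aw must lie in (0, 1], got {self.aw}")
        imbalance = abs(self.ww0 + self.u0 - self.w0)
        if imbalance > MASS_BALANCE_RTOL * self.w0:
            # real-world data rarely balances exactly; warn rather than reject
            warnings.warn(
                f"wet-weight balance off by {imbalance:.3g} g "
                f"(ww0 + u0 = {self.ww0 + self.u0:.6g}, w0 = {self.w0:.6g})",
                MassBalanceWarning,
                stacklevel=2,
            )


@dataclass(frozen=True)
class KineticPoint:
    """One (time, response) point of a kinetic series; ``sd`` is the replicate spread."""

    t: float                  # hours
    Y: float                  # g/g (WL, SG) or kg/kg dry basis (moisture)
    sd: Optional[float] = None

    def __post_init__(self) -> None:
        if self.t < 0:
            raise InvalidMeasurementError(f"time must be non-negative, got {self.t}")


@dataclass(frozen=True)
class KineticSeries:
    """Replicate-averaged response curve at one variety x temperature."""

    variety: str
    temperature: float
    kind: str  # "WL", "SG" or "moisture"
    points: tuple[KineticPoint, ...]

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise ValueError(f"kind must be one of {VALID_KINDS}, got {self.kind!r}")
        times = [p.t for p in self.points]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("point times must be strictly increasing")

    @property
    def t(self) -> np.ndarray:
        return np.array([p.t for p in self.points], dtype=float)

    @property
    def Y(self) -> np.ndarray:
        return np.array([p.Y for p in self.points], dtype=float)


def compute_solid_gain(m: ODMeasurement) -> float:
    """Solid gain SG = (u - u0) / w0, per unit initial sample mass."""
    sg = (m.u - m.u0) / m.w0
    if sg < 0:
        warnings.warn(
            f"negative solid gain {sg:.4g} (u < u0); retained, not clipped",
            NegativeTransferWarning, stacklevel=2)
    return sg


def compute_water_loss(m: ODMeasurement) -> float:
    """Water loss WL = (ww0 - ww) / w0, per unit initial sample mass."""
    wl = (m.ww0 - m.ww) / m.w0
    if wl < 0:
        warnings.warn(
            f"negative water loss {wl:.4g} (ww > ww0); retained, not clipped",
            NegativeTransferWarning, stacklevel=2)
    return wl


def compute_moisture_ratio(M: float, M0: float, Me: float) -> float:
    """Moisture ratio MR = (M - Me) / (M0 - Me).

    Equals 1 at the initial moisture ``M0`` and 0 at equilibrium ``Me``
    (dry-basis moisture contents, kg water / kg dry matter).
    """
    if M0 == Me:
        raise DegenerateSeriesError("M0 == Me: moisture ratio undefined")
    return (M - Me) / (M0 - Me)


def dry_basis_moisture(m: ODMeasurement) -> float:
    """Dry-basis moisture content ww / u (kg water / kg dry matter)."""
    return m.ww / m.u


def _response(m: ODMeasurement, kind: str) -> float:
    if kind == "WL":
        return compute_water_loss(m)
    if kind == "SG":
        return compute_solid_gain(m)
    return dry_basis_moisture(m)


def build_kinetic_series(
    measurements: Sequence[ODMeasurement], kind: str
) -> KineticSeries:
    """Average replicates per time point and assemble a :class:`KineticSeries`.

    WL/SG series are anchored with an exact (t=0, Y=0) point: at time zero no
    transfer has occurred by definition, so any t=0 measurements are replaced
    by the exact anchor.  Replicate sample SDs (ddof=1) are carried for
    reporting only.
    """
    if kind not in VALID_KINDS:
        raise ValueError(f"kind must be one of {VALID_KINDS}, got {kind!r}")
    if not measurements:
        raise InsufficientDataError("no measurements supplied")
    varieties = {m.variety for m in measurements}
    temperatures = {m.temperature for m in measurements}
    if len(varieties) > 1 or len(temperatures) > 1:
        raise GroupingError(
            f"measurements mix varieties {sorted(varieties)} / "
            f"temperatures {sorted(temperatures)}")

    by_time: dict[float, list[float]] = {}
    for m in measurements:
        by_time.setdefault(m.time, []).append(_response(m, kind))

    points: list[KineticPoint] = []
    for t in sorted(by_time):
        vals = np.asarray(by_time[t], dtype=float)
        sd = float(np.std(vals, ddof=1)) if vals.size > 1 else None
        points.append(KineticPoint(t=t, Y=float(vals.mean()), sd=sd))

    if kind in ("WL", "SG"):
        points = [p for p in points if p.t > 0]
        points.insert(0, KineticPoint(t=0.0, Y=0.0, sd=0.0))

    if len(points) < 3:
        raise InsufficientDataError(
            f"need >= 3 distinct time points, got {len(points)}")
    return KineticSeries(
        variety=measurements[0].variety,
        temperature=measurements[0].temperature,
        kind=kind,
        points=tuple(points),
    )


def measurements_to_frame(measurements: Iterable[ODMeasurement]) -> pd.DataFrame:
    """Long-format DataFrame with the canonical CSV columns."""
    rows = [
        (m.variety, m.temperature, m.time, m.replicate,
         m.w0, m.u0, m.u, m.ww0, m.ww,
         np.nan if m.aw is None else m.aw)
        for m in measurements
    ]
    return pd.DataFrame(rows, columns=list(CSV_COLUMNS))


def read_measurements(path) -> list[ODMeasurement]:
    """Read the long-format measurement CSV into validated objects.

    Rows violating hard invariants raise :class:`InvalidMeasurementError`
    carrying the offending row number; soft violations (mass balance) warn.
    """
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c != "aw" and c not in df.columns]
    if missing:
        raise InvalidMeasurementError(f"missing required columns: {missing}")
    has_aw = "aw" in df.columns
    out: list[ODMeasurement] = []
    for i, row in df.iterrows():
        aw = None
        if has_aw and not pd.isna(row["aw"]):
            aw = float(row["aw"])
        try:
            out.append(ODMeasurement(
                variety=str(row["variety"]),
                temperature=float(row["temperature_C"]),
                time=float(row["time_h"]),
                replicate=int(row["replicate"]),
                w0=float(row["w0_g"]), u0=float(row["u0_g"]), u=float(row["u_g"]),
                ww0=float(row["ww0_g"]), ww=float(row["ww_g"]),
                aw=aw,
            ))
        except InvalidMeasurementError as exc:
            raise InvalidMeasurementError(f"row {i}: {exc}") from exc
    return out
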