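"""Forward simulation of the osmotic-dehydration study design.

The study this package models ran four sweet-potato varieties (orange, pink,
purple, white) in 80% sugar-beet molasses at 20/35/50 degC, sampling at 0, 1,
3 and 5 h with n = 3 replicates and a 1:5 sample:solution ratio.  Its raw
data are not published, so every pipeline stage is validated by parameter
recovery on data simulated here from known truths:

* WL/SG kinetics: Peleg curves with the study's reported rate/capacity
  constants, plus additive Gaussian measurement noise (none at t = 0, where
  the measurement is the initial state itself);
* masses reconstructed as exact inverses of the SG/WL definitions
  (w0 fixed, u = u0 + SG*w0, ww = ww0 - WL*w0, with ww0 + u0 = w0 exactly);
* water activity emitted by inverting the GAB isotherm at the simulated
  dry-basis moisture divided by ``sorption_moisture_scale`` (the reported
  isotherm parameters describe a low-moisture sorption regime, two orders of
  magnitude below osmotic moisture contents), plus Gaussian noise;
* drying families: first-term Fick-slab moisture-ratio curves with Deff(T)
  from an Arrhenius law, under multiplicative log-normal noise.

All draws are fixed by the config seed; identical configs give identical
outputs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .diffusivity import GAS_CONSTANT, MoistureSeries, predict_mr, SECONDS_PER_HOUR
from .gab import GABFit, IsothermPoint, invert_gab, predict_gab
from .mass_transfer import KineticPoint, KineticSeries, ODMeasurement

__all__ = [
    "SyntheticConfig",
    "PELEG_CONSTANTS",
    "GAB_CONSTANTS",
    "ACTIVATION_ENERGY_KJMOL",
    "DEFF_ENDPOINTS",
    "arrhenius_truth",
    "generate_od_experiment",
    "generate_kinetic_series",
    "generate_isotherm",
    "generate_drying_family",
    "write_truth_ledger",
]

VARIETIES = ("orange", "pink", "purple", "white")
TEMPERATURES = (20.0, 35.0, 50.0)
TIMES_H = (0.0, 1.0, 3.0, 5.0)

#: study-reported Peleg constants (kind, variety, temperature degC) -> (k1, k2)
PELEG_CONSTANTS: dict[tuple[str, str, float], tuple[float, float]] = {
    ("WL", "orange", 20.0): (1.767, 1.073),
    ("WL", "orange", 35.0): (0.879, 1.226),
    ("WL", "orange", 50.0): (0.676, 1.180),
    ("WL", "pink", 20.0): (1.595, 1.220),
    ("WL", "pink", 35.0): (0.718, 1.254),
    ("WL", "pink", 50.0): (0.697, 1.155),
    ("WL", "purple", 20.0): (2.894, 1.446),
    ("WL", "purple", 35.0): (1.960, 1.441),
    ("WL", "purple", 50.0): (1.974, 1.252),
    ("WL", "white", 20.0): (1.881, 1.055),
    ("WL", "white", 35.0): (1.568, 1.011),
    ("WL", "white", 50.0): (0.897, 1.105),
    ("SG", "orange", 20.0): (5.205, 5.837),
    ("SG", "orange", 35.0): (5.485, 5.186),
    ("SG", "orange", 50.0): (4.833, 4.683),
    ("SG", "pink", 20.0): (4.866, 6.683),
    ("SG", "pink", 35.0): (5.030, 5.079),
    ("SG", "pink", 50.0): (5.189, 4.038),
    ("SG", "purple", 20.0): (27.766, 4.553),
    ("SG", "purple", 35.0): (24.283, 3.073),
    ("SG", "purple", 50.0): (12.961, 4.782),
    ("SG", "white", 20.0): (9.361, 7.469),
    ("SG", "white", 35.0): (6.670, 7.276),
    ("SG", "white", 50.0): (6.589, 6.866),
}

#: study-reported GAB parameters (variety, temperature degC) -> (Xm, C, K)
GAB_CONSTANTS: dict[tuple[str, float], tuple[float, float, float]] = {
    ("orange", 20.0): (0.012, 2.185, 0.937),
    ("orange", 35.0): (0.043, 2.021, 0.863),
    ("orange", 50.0): (0.017, 2.113, 0.903),
    ("pink", 20.0): (0.027, 1.997, 0.855),
    ("pink", 35.0): (0.028, 2.178, 0.933),
    ("pink", 50.0): (0.004, 2.205, 0.944),
    ("purple", 20.0): (0.021, 2.223, 0.955),
    ("purple", 35.0): (0.020, 2.168, 0.929),
    ("purple", 50.0): (0.023, 2.257, 0.969),
    ("white", 20.0): (0.038, 2.185, 0.938),
    ("white", 35.0): (0.037, 2.162, 0.927),
    ("white", 50.0): (0.017, 2.297, 0.980),
}

#: study-reported activation energies, kJ/mol
ACTIVATION_ENERGY_KJMOL: dict[str, float] = {
    "orange": 12.873,
    "pink": 15.915,
    "purple": 16.652,
    "white": 7.096,
}

#: study-reported Deff endpoints (m^2/s before scaling): variety -> (20 degC, 50 degC)
DEFF_ENDPOINTS: dict[str, tuple[float, float]] = {
    "orange": (2.92, 4.83),
    "pink": (2.14, 3.96),
    "purple": (1.85, 3.54),
    "white": (3.55, 4.68),
}

#: default exponent scale for the Deff endpoint values above
DEFF_SCALE = 1e-10


def arrhenius_truth(variety: str, deff_scale: float = DEFF_SCALE) -> tuple[float, float]:
    """(D0 m^2/s, Ea kJ/mol) anchored at the variety's 20 degC diffusivity."""
    ea = ACTIVATION_ENERGY_KJMOL[variety]
    d20 = DEFF_ENDPOINTS[variety][0] * deff_scale
    d0 = d20 * np.exp(ea * 1000.0 / (GAS_CONSTANT * 293.15))
    return float(d0), ea


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design simulation settings; defaults reproduce the study layout."""

    varieties: tuple[str, ...] = VARIETIES
    temperatures: tuple[float, ...] = TEMPERATURES
    times: tuple[float, ...] = TIMES_H
    n_replicates: int = 3
    #: (kind, variety, T) -> (k1, k2); None -> the study constants
    true_peleg: Optional[dict] = None
    #: (variety, T) -> (Xm, C, K); None -> the study constants
    true_gab: Optional[dict] = None
    w0: float = 10.0                  # g, fixed initial sample weight
    water_fraction0: float = 0.8      # initial water mass fraction (ww0/w0)
    noise_sd_wl: float = 0.01         # g/g additive on WL
    noise_sd_sg: float = 0.002        # g/g additive on SG
    noise_sd_aw: float = 0.01         # additive on aw
    noise_logsd_deff: float = 0.02    # log-normal on MR curves
    half_thickness_L: float = 0.0025  # m
    #: dry-basis moisture is divided by this before GAB inversion
    sorption_moisture_scale: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not (0 < self.water_fraction0 < 1):
            raise ValueError("water_fraction0 must lie in (0, 1)")
        if self.w0 <= 0 or self.half_thickness_L <= 0:
            raise ValueError("w0 and half_thickness_L must be positive")

    def peleg(self, kind: str, variety: str, T: float) -> tuple[float, float]:
        table = self.true_peleg if self.true_peleg is not None else PELEG_CONSTANTS
        return table[(kind, variety, T)]

    def gab(self, variety: str, T: float) -> tuple[float, float, float]:
        table = self.true_gab if self.true_gab is not None else GAB_CONSTANTS
        return table[(variety, T)]


def _peleg_value(t: float, k1: float, k2: float) -> float:
    return 0.0 if t == 0 else t / (k1 + k2 * t)


def generate_kinetic_series(k1: float, k2: float, times: Sequence[float],
                            noise_sd: float, seed: int,
                            kind: str = "WL", variety: str = "synthetic",
                            temperature: float = 20.0) -> KineticSeries:
    """One Peleg series with additive Gaussian noise at positive times.

    The t = 0 point is the exact (0, 0) anchor (appended if absent from
    ``times``).
    """
    rng = np.random.default_rng(seed)
    ts = sorted(set(float(t) for t in times) | {0.0})
    points = []
    for t in ts:
        y = _peleg_value(t, k1, k2)
        if t > 0 and noise_sd > 0:
            y += rng.normal(0.0, noise_sd)
        points.append(KineticPoint(t=t, Y=y))
    return KineticSeries(variety=variety, temperature=temperature,
                         kind=kind, points=tuple(points))


def generate_od_experiment(
    config: SyntheticConfig,
) -> tuple[list[ODMeasurement], dict]:
    """Simulate the full factorial design; returns (measurements, truth ledger).

    Replicate rows are exact inverses of the SG/WL definitions, so the
    mass-transfer stage recovers the simulated responses identically and,
    at zero noise, downstream Peleg fits recover the generating constants.
    """
    rng = np.random.default_rng(config.seed)
    u0 = config.w0 * (1.0 - config.water_fraction0)
    ww0 = config.w0 - u0   # exact wet-weight balance

    measurements: list[ODMeasurement] = []
    n_negative = 0
    n_draws = 0
    for variety in config.varieties:
        for T in config.temperatures:
            k1w, k2w = config.peleg("WL", variety, T)
            k1s, k2s = config.peleg("SG", variety, T)
            gab_fit = GABFit.from_parameters(*config.gab(variety, T))
            for t in config.times:
                for rep in range(1, config.n_replicates + 1):
                    wl = _peleg_value(t, k1w, k2w)
                    sg = _peleg_value(t, k1s, k2s)
                    if t > 0:
                        wl += rng.normal(0.0, config.noise_sd_wl)
                        sg += rng.normal(0.0, config.noise_sd_sg)
                        n_draws += 1
                        if wl < 0:
                            n_negative += 1
                    u = u0 + sg * config.w0
                    ww = max(ww0 - wl * config.w0, 0.0)
                    aw = _emit_aw(gab_fit, ww / u, config, rng)
                    measurements.append(ODMeasurement(
                        variety=variety, temperature=T, time=t, replicate=rep,
                        w0=config.w0, u0=u0, u=u, ww0=ww0, ww=ww, aw=aw))
    if n_draws and n_negative > 0.5 * n_draws:
        warnings.warn(
            f"noise produced negative WL in {n_negative}/{n_draws} draws; "
            "noise_sd_wl is likely too large for this design",
            UserWarning, stacklevel=2)

    truth = {
        "seed": config.seed,
        "design": {
            "varieties": list(config.varieties),
            "temperatures": list(config.temperatures),
            "times_h": list(config.times),
            "n_replicates": config.n_replicates,
            "w0_g": config.w0,
            "water_fraction0": config.water_fraction0,
        },
        "noise": {
            "sd_wl": config.noise_sd_wl,
            "sd_sg": config.noise_sd_sg,
            "sd_aw": config.noise_sd_aw,
        },
        "sorption_moisture_scale": config.sorption_moisture_scale,
        "peleg": {
            f"{kind}/{v}/{T:g}": config.peleg(kind, v, T)
            for kind in ("WL", "SG")
            for v in config.varieties for T in config.temperatures
        },
        "gab": {
            f"{v}/{T:g}": config.gab(v, T)
            for v in config.varieties for T in config.temperatures
        },
    }
    return measurements, truth


def _emit_aw(gab_fit: GABFit, moisture: float, config: SyntheticConfig,
             rng: np.random.Generator) -> float:
    """Water activity from GAB inversion of scaled dry-basis moisture."""
    x = moisture / config.sorption_moisture_scale
    aw_hi = min(1.0, 1.0 / gab_fit.K) * (1.0 - 1e-9)
    x_hi = predict_gab(gab_fit, aw_hi)
    aw = aw_hi if x >= x_hi else invert_gab(gab_fit, x) if x > 0 else 1e-6
    if config.noise_sd_aw > 0:
        aw += rng.normal(0.0, config.noise_sd_aw)
    return float(np.clip(aw, 1e-6, 1.0 - 1e-6))


def generate_isotherm(params: tuple[float, float, float], aw_grid: Sequence[float],
                      noise_sd: float, seed: int) -> list[IsothermPoint]:
    """Noisy isotherm points x = GAB(aw) + N(0, noise_sd), truncated at 0."""
    Xm, C, K = params
    grid = np.asarray(aw_grid, dtype=float)
    if K * float(np.max(grid)) >= 1:
        raise ValueError("K * max(aw_grid) must be < 1")
    fit = GABFit.from_parameters(Xm, C, K)
    rng = np.random.default_rng(seed)
    pts = []
    for aw in grid:
        x = predict_gab(fit, float(aw))
        if noise_sd > 0:
            x += rng.normal(0.0, noise_sd)
        pts.append(IsothermPoint(aw=float(aw), x=max(float(x), 0.0)))
    return pts


def generate_drying_family(
    variety_params: tuple[float, float], temperatures: Sequence[float],
    times: Sequence[float], L: float, noise_logsd: float, seed: int,
    M0: float = 4.0, Me: float = 0.2, variety: str = "synthetic",
) -> list[MoistureSeries]:
    """Moisture series at several temperatures from one Arrhenius truth.

    ``variety_params`` is (D0 m^2/s, Ea kJ/mol); Deff(T) follows the
    Arrhenius law, moisture-ratio curves follow the first-term slab solution
    with multiplicative log-normal noise, and moisture is reconstructed as
    M = Me + MR * (M0 - Me).
    """
    D0, Ea = variety_params
    if not (D0 > 0 and L > 0):
        raise ValueError("D0 and L must be positive")
    rng = np.random.default_rng(seed)
    out = []
    for T in temperatures:
        deff = D0 * np.exp(-Ea * 1000.0 / (GAS_CONSTANT * (T + 273.15)))
        pts = []
        for t in times:
            mr = predict_mr(deff, L, t * SECONDS_PER_HOUR)
            if noise_logsd > 0:
                mr *= np.exp(rng.normal(0.0, noise_logsd))
            pts.append((float(t), float(Me + mr * (M0 - Me))))
        out.append(MoistureSeries(variety=variety, temperature=float(T),
                                  points=tuple(pts), M0=M0, Me=Me))
    return out


def write_truth_ledger(truth: dict, path) -> None:
    """Serialise the generating-parameter ledger as JSON."""
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
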