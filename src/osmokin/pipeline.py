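"""End-to-end analysis pipeline: raw CSV -> fitted tables -> report bundle.

Stages run in the order the method proceeds: input validation, mass-transfer
reduction, Peleg kinetics per (variety, temperature, response), GAB isotherm
per (variety, temperature), effective diffusivity per (variety, temperature),
Arrhenius activation energy per variety.  The bundle mirrors the field's
conventional report layout: a Peleg-constant table with derived initial rates
and equilibria, a Peleg diagnostics table, a GAB-coefficient table with the
C*K product, a GAB diagnostics table, a diffusivity table and an
activation-energy table, plus a JSON manifest.

The pipeline is a pure function of (input file, config): identical inputs
give byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .diffusivity import ArrheniusFit, DiffusivityFit, MoistureSeries, estimate_deff, fit_arrhenius
from .gab import GABFit, IsothermPoint, fit_gab
from .mass_transfer import (
    InsufficientDataError,
    MassBalanceWarning,
    ODMeasurement,
    build_kinetic_series,
    dry_basis_moisture,
    read_measurements,
)
from .metrics import FitDiagnostics
from .peleg import PelegFit, fit_peleg

logger = logging.getLogger("osmokin")

__all__ = [
    "RunConfig",
    "ValidationReport",
    "PipelineResult",
    "validate_input",
    "run_full_pipeline",
    "peleg_stage",
    "gab_stage",
    "diffusivity_stage",
    "arrhenius_stage",
]


@dataclass(frozen=True)
class RunConfig:
    """Settings for one pipeline run."""

    input_path: str
    output_dir: str
    half_thickness_L: float = 0.0025       # m, slab half-thickness
    gab_restarts: int = 64
    seed: int = 0
    ci_level: float = 0.95
    sorption_moisture_scale: float = 100.0
    formats: tuple[str, ...] = ("csv", "json")

    def __post_init__(self) -> None:
        if not (0 < self.ci_level < 1):
            raise ValueError("ci_level must lie in (0, 1)")
        if self.gab_restarts < 1:
            raise ValueError("gab_restarts must be >= 1")
        if self.half_thickness_L <= 0:
            raise ValueError("half_thickness_L must be positive")


@dataclass
class ValidationReport:
    n_rows: int = 0
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors and self.n_rows > 0


@dataclass
class PipelineResult:
    """In-memory report bundle; DataFrames carry full precision."""

    peleg_table: pd.DataFrame
    peleg_diagnostics: pd.DataFrame
    gab_table: Optional[pd.DataFrame]
    gab_diagnostics: Optional[pd.DataFrame]
    deff_table: pd.DataFrame
    arrhenius_table: pd.DataFrame
    manifest: dict


def validate_input(path) -> ValidationReport:
    """Row-by-row invariant checks of the long-format measurement CSV."""
    report = ValidationReport()
    try:
        df = pd.read_csv(path)
    except (OSError, ValueError) as exc:
        report.errors.append(f"unreadable input: {exc}")
        return report
    report.n_rows = len(df)
    if report.n_rows == 0:
        report.errors.append("zero usable rows")
        return report
    for i, row in df.iterrows():
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                aw = row.get("aw")
                ODMeasurement(
                    variety=str(row["variety"]),
                    temperature=float(row["temperature_C"]),
                    time=float(row["time_h"]),
                    replicate=int(row["replicate"]),
                    w0=float(row["w0_g"]), u0=float(row["u0_g"]),
                    u=float(row["u_g"]),
                    ww0=float(row["ww0_g"]), ww=float(row["ww_g"]),
                    aw=None if aw is None or pd.isna(aw) else float(aw),
                )
            for w in caught:
                report.warnings.append(f"row {i}: {w.message}")
        except (ValueError, KeyError) as exc:
            report.errors.append(f"row {i}: {exc}")
    return report


def _groups(measurements: Sequence[ODMeasurement]):
    """Yield (variety, temperature, rows) in deterministic sorted order."""
    keys = sorted({(m.variety, m.temperature) for m in measurements})
    for variety, T in keys:
        yield variety, T, [m for m in measurements
                           if m.variety == variety and m.temperature == T]


def _diag_row(d: Optional[FitDiagnostics]) -> dict:
    if d is None:
        return {k: np.nan for k in ("chi2", "RMSE", "MBE", "MPE", "SSE", "AARD", "r2")}
    return {"chi2": d.chi2, "RMSE": d.rmse, "MBE": d.mbe, "MPE": d.mpe,
            "SSE": d.sse, "AARD": d.aard, "r2": d.r2}


def peleg_stage(measurements: Sequence[ODMeasurement],
                ci_level: float = 0.95):
    """Fit Peleg WL and SG models per condition.

    Returns (constants table, diagnostics table, fits keyed by
    (kind, variety, T)).  Per-condition failures are logged and excluded.
    """
    rows, diag_rows = [], []
    fits: dict[tuple[str, str, float], PelegFit] = {}
    for variety, T, group in _groups(measurements):
        for kind in ("WL", "SG"):
            try:
                series = build_kinetic_series(group, kind)
                fit = fit_peleg(series, ci_level=ci_level)
            except Exception as exc:
                logger.warning("Peleg %s fit failed for %s @ %g degC: %s",
                               kind, variety, T, exc)
                continue
            fits[(kind, variety, T)] = fit
            rows.append({
                "kind": kind, "variety": variety, "temperature_C": T,
                "k1": fit.k1, "k1_ci_lo": fit.k1_ci95[0], "k1_ci_hi": fit.k1_ci95[1],
                "k2": fit.k2, "k2_ci_lo": fit.k2_ci95[0], "k2_ci_hi": fit.k2_ci95[1],
                "initial_rate": fit.initial_rate, "equilibrium": fit.equilibrium,
            })
            diag_rows.append({"kind": kind, "variety": variety,
                              "temperature_C": T, **_diag_row(fit.diagnostics)})
    return pd.DataFrame(rows), pd.DataFrame(diag_rows), fits


def gab_stage(measurements: Sequence[ODMeasurement],
              sorption_moisture_scale: float = 100.0,
              n_restarts: int = 64, seed: int = 0, ci_level: float = 0.95):
    """Fit the GAB isotherm per condition from (aw, scaled moisture) pairs.

    Returns (coefficient table, diagnostics table, fits); None tables when
    the input carries no water-activity data.
    """
    if all(m.aw is None for m in measurements):
        logger.info("no water-activity data: GAB stage skipped")
        return None, None, {}
    rows, diag_rows = [], []
    fits: dict[tuple[str, float], GABFit] = {}
    for variety, T, group in _groups(measurements):
        pts = [IsothermPoint(aw=m.aw,
                             x=dry_basis_moisture(m) / sorption_moisture_scale)
               for m in group if m.aw is not None]
        try:
            if len(pts) < 3:
                raise InsufficientDataError(f"only {len(pts)} aw points")
            fit = fit_gab(pts, n_restarts=n_restarts, seed=seed,
                          ci_level=ci_level, variety=variety, temperature=T)
        except Exception as exc:
            logger.warning("GAB fit failed for %s @ %g degC: %s", variety, T, exc)
            continue
        fits[(variety, T)] = fit
        rows.append({
            "variety": variety, "temperature_C": T,
            "C": fit.C, "C_ci_lo": fit.C_ci95[0], "C_ci_hi": fit.C_ci95[1],
            "K": fit.K, "K_ci_lo": fit.K_ci95[0], "K_ci_hi": fit.K_ci95[1],
            "Xm": fit.Xm, "Xm_ci_lo": fit.Xm_ci95[0], "Xm_ci_hi": fit.Xm_ci95[1],
            "CK_product": fit.ck_product,
        })
        diag_rows.append({"variety": variety, "temperature_C": T,
                          **_diag_row(fit.diagnostics)})
    return pd.DataFrame(rows), pd.DataFrame(diag_rows), fits


def diffusivity_stage(measurements: Sequence[ODMeasurement],
                      peleg_fits: dict, L: float):
    """Estimate per-condition Deff from dry-basis moisture curves.

    The equilibrium moisture Me comes from the condition's Peleg equilibria:
    Me = (ww0 - WL_inf*w0) / (u0 + SG_inf*w0), evaluated at the replicate
    means of the initial masses.
    """
    rows = []
    fits: dict[tuple[str, float], DiffusivityFit] = {}
    for variety, T, group in _groups(measurements):
        try:
            series = build_kinetic_series(group, "moisture")
            t0 = [p for p in series.points if p.t == 0]
            if not t0:
                raise InsufficientDataError("no t = 0 moisture point")
            M0 = t0[0].Y
            wl_fit = peleg_fits.get(("WL", variety, T))
            sg_fit = peleg_fits.get(("SG", variety, T))
            if wl_fit is None or sg_fit is None:
                raise InsufficientDataError("missing Peleg equilibria for Me")
            w0 = float(np.mean([m.w0 for m in group]))
            u0 = float(np.mean([m.u0 for m in group]))
            ww0 = float(np.mean([m.ww0 for m in group]))
            me = (ww0 - wl_fit.equilibrium * w0) / (u0 + sg_fit.equilibrium * w0)
            me = max(me, 0.0)
            mseries = MoistureSeries(
                variety=variety, temperature=T,
                points=tuple((p.t, p.Y) for p in series.points),
                M0=M0, Me=me)
            fit = estimate_deff(mseries, L)
        except Exception as exc:
            logger.warning("diffusivity fit failed for %s @ %g degC: %s",
                           variety, T, exc)
            continue
        fits[(variety, T)] = fit
        rows.append({"variety": variety, "temperature_C": T,
                     "Deff_m2s": fit.Deff, "L_m": fit.L,
                     "intercept": fit.intercept, "r2": fit.r2,
                     "n_points": fit.n_points, "n_excluded": fit.n_excluded})
    return pd.DataFrame(rows), fits


def arrhenius_stage(deff_fits: dict, ci_level: float = 0.95):
    """Arrhenius regression per variety across temperatures."""
    rows = []
    fits: dict[str, ArrheniusFit] = {}
    varieties = sorted({v for v, _ in deff_fits})
    for variety in varieties:
        pairs = sorted((T, f.Deff) for (v, T), f in deff_fits.items() if v == variety)
        try:
            fit = fit_arrhenius(pairs, ci_level=ci_level, variety=variety)
        except Exception as exc:
            logger.warning("Arrhenius fit failed for %s: %s", variety, exc)
            continue
        fits[variety] = fit
        rows.append({"variety": variety, "Ea_kJmol": fit.Ea,
                     "Ea_sd": fit.Ea_sd,
                     "Ea_ci_lo": fit.Ea_ci95[0], "Ea_ci_hi": fit.Ea_ci95[1],
                     "D0_m2s": fit.D0, "r2": fit.r2, "n_points": fit.n_points})
    return pd.DataFrame(rows), fits


def _format_peleg(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for c in out.columns:
        if out[c].dtype.kind == "f":
            out[c] = out[c].round(3)
    return out


def _format_diag(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for c in ("chi2", "RMSE", "MBE", "MPE", "SSE", "AARD"):
        if c in out.columns:
            out[c] = out[c].map(lambda v: f"{v:.3e}" if np.isfinite(v) else "")
    if "r2" in out.columns:
        out["r2"] = out["r2"].round(4)
    return out


def run_full_pipeline(config: RunConfig) -> PipelineResult:
    """Run validation and all fitting stages; write the report bundle.

    Validation failures abort with row-numbered messages; per-condition fit
    failures are logged and excluded without aborting the run.
    """
    report = validate_input(config.input_path)
    if not report.ok:
        raise ValueError("input validation failed:\n" + "\n".join(report.errors))
    for msg in report.warnings:
        logger.warning("validation: %s", msg)

    measurements = read_measurements(config.input_path)

    peleg_tab, peleg_diag, peleg_fits = peleg_stage(measurements, config.ci_level)
    gab_tab, gab_diag, _gab_fits = gab_stage(
        measurements, config.sorption_moisture_scale,
        config.gab_restarts, config.seed, config.ci_level)
    deff_tab, deff_fits = diffusivity_stage(
        measurements, peleg_fits, config.half_thickness_L)
    arr_tab, _arr_fits = arrhenius_stage(deff_fits, config.ci_level)

    manifest = {
        "software": {"name": "osmokin", "version": __version__},
        "config": asdict(config),
        "rows": {
            "input": len(measurements),
            "peleg_fits": len(peleg_fits),
            "gab_fits": len(_gab_fits),
            "deff_fits": len(deff_fits),
            "arrhenius_fits": len(_arr_fits),
        },
        "half_thickness_L_m": config.half_thickness_L,
        "validation_warnings": report.warnings,
    }

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if "csv" in config.formats:
        _format_peleg(peleg_tab).to_csv(out / "peleg_constants.csv", index=False)
        _format_diag(peleg_diag).to_csv(out / "peleg_diagnostics.csv", index=False)
        if gab_tab is not None:
            _format_peleg(gab_tab).to_csv(out / "gab_coefficients.csv", index=False)
            _format_diag(gab_diag).to_csv(out / "gab_diagnostics.csv", index=False)
        deff_tab.to_csv(out / "effective_diffusivity.csv", index=False)
        _format_peleg(arr_tab).to_csv(out / "activation_energy.csv", index=False)
    if "json" in config.formats:
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")

    return PipelineResult(
        peleg_table=peleg_tab, peleg_diagnostics=peleg_diag,
        gab_table=gab_tab, gab_diagnostics=gab_diag,
        deff_table=deff_tab, arrhenius_table=arr_tab, manifest=manifest)
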