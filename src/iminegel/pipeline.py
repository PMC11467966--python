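"""End-to-end orchestration: raw traces -> REC tables -> predictions.

Two entry points compose the library in measurement order:

* :func:`run_rec_pipeline` — per-trace preprocessing (background
  subtraction, Beer-Lambert inversion, amine-consumption conversion),
  kinetic fitting with the automatic constrained-pathway fallback, and
  replicate aggregation into a REC table.
* :func:`run_prediction_pipeline` — cross-link fraction curves, the
  competitive softening map with its maximal-softening location, bound
  fraction isotherms, and anchored shear-modulus predictions.

Every run can write its resolved config, a provenance stamp (config
hash, package version, seed) and the stage outputs to an output
directory; identical config + inputs reproduce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import __version__, kinetics, spectro
from .equilibrium import (
    CompetitiveSystem,
    bound_fraction_isotherm,
    fraction_vs_ratio_curve,
    softening_map,
)
from .mechanics import relative_softening_prediction

logger = logging.getLogger(__name__)

__all__ = ["TraceInput", "RecPipelineConfig", "PredictionConfig",
           "run_rec_pipeline", "run_prediction_pipeline"]


class TraceInput(BaseModel):
    """One measured trace: either a wide spectral CSV (kind='spectral')
    or a preprocessed concentration CSV (kind='concentration')."""

    path: str
    x0: float = Field(gt=0)  # mol/L initial amine concentration
    label: str  # e.g. "2+5"; replicates share a label
    kind: str = "spectral"  # spectral | concentration
    epsilon: float | None = None  # L/mol/cm, required for spectral input
    detection_wavelength: float = 240.0  # nm
    path_length: float = 1.0  # cm
    dead_time: float = 0.0  # s


class RecPipelineConfig(BaseModel):
    traces: list[TraceInput]
    aggregation: str = "per_replicate_mean"
    constrain_threshold: float = 1.0  # rel. SE on k_minus1 triggering the constrained fit
    fit_offset: bool = True  # absorb background-subtraction offset in the fit
    output_dir: str | None = None
    seed: int = 0
    log_level: str = "INFO"


class PredictionConfig(BaseModel):
    ald0: float = Field(default=10.1e-3, gt=0)  # mol/L
    curve_keqs: list[float] = Field(
        default_factory=lambda: [1e1, 1e2, 1e3, 1e4, 1e5, 1e6, 1e7])
    softening_grid_points: int = 121
    softening_keq_range: tuple[float, float] = (1e1, 1e7)
    chi1: float = 0.5
    chi2: float = 0.5
    isotherm_x0: float = 10.1e-3
    series_keqs: tuple[float, float] | None = (1.3e3, 1.0e2)
    series_chi2_schedule: list[float] = Field(
        default_factory=lambda: [0.0, 0.1, 0.2, 0.3, 0.4, 0.5])
    anchor_G: float = 2200.0  # Pa
    output_dir: str | None = None
    seed: int = 0


def _provenance(config: BaseModel) -> dict:
    resolved = config.model_dump_json()
    return {
        "config_sha256": hashlib.sha256(resolved.encode()).hexdigest(),
        "package_version": __version__,
        "seed": getattr(config, "seed", None),
    }


def _load_amine_trace(ti: TraceInput) -> spectro.ConcentrationTrace:
    if ti.kind == "concentration":
        return spectro.ConcentrationTrace.from_csv(
            ti.path, species="amine", x0=ti.x0, label=ti.label)
    if ti.kind != "spectral":
        raise ValueError(f"unknown trace kind {ti.kind!r} for {ti.path}")
    if ti.epsilon is None:
        raise ValueError(f"spectral input {ti.path} needs epsilon")
    series = spectro.SpectralSeries.from_csv(
        ti.path, path_length=ti.path_length, dead_time=ti.dead_time)
    corrected = spectro.preprocess_uvvis_series(series, ti.detection_wavelength)
    calib = spectro.AbsorptivityCalibration(
        epsilon=ti.epsilon, detection_wavelength=ti.detection_wavelength,
        path_length=ti.path_length, fit_r2=1.0,
        calibration_points=[(0.0, 0.0), (1.0, ti.epsilon)])
    imine = spectro.absorbance_to_concentration(corrected, calib)
    return spectro.amine_consumption_trace(imine, ti.x0)


def run_rec_pipeline(config: RecPipelineConfig
                     ) -> tuple[pd.DataFrame, dict[str, list[kinetics.FitResult]]]:
    """Fit every input trace and aggregate replicates into a REC table.

    Returns the table (one row per label) and the per-label fit results.
    Any stage failure aborts with the stage name and offending input.
    """
    logging.basicConfig(level=config.log_level)
    if not config.traces:
        raise ValueError("no input traces configured")
    fits: dict[str, list[kinetics.FitResult]] = {}
    for ti in config.traces:
        try:
            amine = _load_amine_trace(ti)
        except Exception as exc:
            raise RuntimeError(
                f"preprocessing failed for {ti.path!r}: {exc}") from exc
        try:
            fit = kinetics.fit_auto(amine, config.constrain_threshold,
                                    fit_offset=config.fit_offset)
        except Exception as exc:
            raise RuntimeError(
                f"kinetic fit failed for {ti.path!r}: {exc}") from exc
        logger.info("fitted %s (%s): k1=%.4g k-1=%.4g flags=%s", ti.label,
                    ti.path, fit.parameters.k1, fit.parameters.k_minus1,
                    fit.flags)
        fits.setdefault(ti.label, []).append(fit)

    rows = []
    for label, group in fits.items():
        rc = kinetics.aggregate_replicates(group, config.aggregation) \
            if len(group) > 1 else kinetics.aggregate_replicates(group)
        rows.append({
            "label": label, "n_replicates": rc.n_replicates,
            "k1_L_mol_s": rc.k1, "k1_sd": rc.k1_uncertainty,
            "k_minus1_s": rc.k_minus1, "k_minus1_sd": rc.k_minus1_uncertainty,
            "Keq_L_mol": rc.Keq, "Keq_sd": rc.Keq_uncertainty,
            "method": rc.method, "aggregation": rc.aggregation,
        })
    table = pd.DataFrame(rows)
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "rec_table.tsv", sep="\t", index=False)
        (out / "run.json").write_text(json.dumps(
            {"provenance": _provenance(config),
             "config": config.model_dump()}, indent=2, default=str))
    return table, fits


def run_prediction_pipeline(config: PredictionConfig) -> dict:
    """Compute the equilibrium-model outputs: fraction-vs-ratio curves,
    the softening map + maximal-softening report, the bound-fraction
    isotherm and (optionally) an anchored predicted-G' titration series."""
    results: dict = {"provenance": _provenance(config)}
    curves = {}
    for keq in config.curve_keqs:
        curves[keq] = fraction_vs_ratio_curve(keq, config.ald0)
    results["fraction_curves"] = curves

    lo, hi = config.softening_keq_range
    grid = np.logspace(np.log10(lo), np.log10(hi), config.softening_grid_points)
    surface, report = softening_map(grid, grid, chi1=config.chi1,
                                    chi2=config.chi2, ald0=config.ald0)
    if report["n_negative_cells"] == 0:
        logger.warning("softening map has no negative region")
    results["softening_surface"] = surface
    results["softening_report"] = report

    results["isotherm"] = bound_fraction_isotherm(config.isotherm_x0)

    if config.series_keqs is not None:
        k1, k2 = config.series_keqs
        systems = [CompetitiveSystem.from_keq(
            config.ald0, config.chi1 * config.ald0, chi2 * config.ald0, k1, k2)
            for chi2 in config.series_chi2_schedule]
        g = relative_softening_prediction(systems, config.anchor_G)
        results["predicted_G_series"] = pd.DataFrame({
            "chi1": config.chi1, "chi2": config.series_chi2_schedule,
            "predicted_G_Pa": g})

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        for keq, c in curves.items():
            c.to_dataframe().to_csv(out / f"fraction_curve_keq{keq:g}.csv",
                                    index=False)
        surface.to_dataframe().to_csv(out / "softening_map.csv", index=False)
        results["isotherm"].to_dataframe().to_csv(out / "isotherm.csv",
                                                  index=False)
        if "predicted_G_series" in results:
            results["predicted_G_series"].to_csv(
                out / "predicted_G_series.tsv", sep="\t", index=False)
        (out / "softening_report.json").write_text(
            json.dumps({**report, "provenance": results["provenance"]},
                       indent=2))
    return results
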