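"""Spectroscopic preprocessing: absorbance to concentration.

Converts raw UV-vis measurements of imine formation into the molar
concentration traces that the kinetic model consumes, and handles the
supporting calibration arithmetic: Beer-Lambert molar absorptivity
(A = eps * c * l), Schiff-test serial dilutions, degree of oxidation of
oxidized polysaccharides, and macromer aldehyde concentrations.

All concentrations are stored internally in mol/L; CSV I/O accepts
``concentration_M`` / ``_mM`` / ``_uM`` columns.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "SpectralSeries",
    "ConcentrationTrace",
    "AbsorptivityCalibration",
    "FormulationSpec",
    "preprocess_uvvis_series",
    "fit_molar_absorptivity",
    "absorbance_to_concentration",
    "amine_consumption_trace",
    "schiff_standard_concentrations",
    "degree_of_oxidation",
    "macromer_aldehyde_concentration",
]


def _strictly_increasing(a: np.ndarray) -> bool:
    return a.size < 2 or bool(np.all(np.diff(a) > 0))


@dataclass
class SpectralSeries:
    """A(lambda, t) matrix acquired on a scanning spectrophotometer.

    ``absorbance`` is indexed [time, wavelength]; ``dead_time`` is added to
    all times (acquisition typically starts a known interval after mixing).
    """

    wavelengths: np.ndarray  # nm, ascending
    times: np.ndarray  # s since mixing
    absorbance: np.ndarray  # a.u., shape (n_times, n_wavelengths)
    path_length: float = 1.0  # cm
    dead_time: float = 0.0  # s, added to times
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.times = np.asarray(self.times, dtype=float) + float(self.dead_time)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if not _strictly_increasing(self.wavelengths):
            raise ValueError("wavelengths must be strictly increasing")
        if not _strictly_increasing(self.times):
            raise ValueError("times must be strictly increasing")
        if self.absorbance.shape != (self.times.size, self.wavelengths.size):
            raise ValueError(
                f"absorbance shape {self.absorbance.shape} does not match "
                f"(n_times={self.times.size}, n_wavelengths={self.wavelengths.size})"
            )
        if self.path_length <= 0:
            raise ValueError("path_length must be positive")

    @classmethod
    def from_csv(cls, path, path_length: float = 1.0, dead_time: float = 0.0,
                 **metadata) -> "SpectralSeries":
        """Read a wide CSV: first column ``time_s``, remaining columns named
        by wavelength in nm."""
        df = pd.read_csv(path)
        if df.columns[0] != "time_s":
            raise ValueError("first column must be 'time_s'")
        wavelengths = np.array([float(c) for c in df.columns[1:]])
        order = np.argsort(wavelengths)
        return cls(
            wavelengths=wavelengths[order],
            times=df["time_s"].to_numpy(),
            absorbance=df.iloc[:, 1:].to_numpy()[:, order],
            path_length=path_length,
            dead_time=dead_time,
            metadata=metadata,
        )

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.absorbance, columns=[f"{w:g}" for w in self.wavelengths])
        df.insert(0, "time_s", self.times)
        df.to_csv(path, index=False)


@dataclass
class ConcentrationTrace:
    """A species' molar concentration sampled in time.

    ``x0`` is the initial concentration of the limiting reactant (the amine
    for consumption traces) and is required by the kinetic fit.
    """

    times: np.ndarray  # s
    concentration: np.ndarray  # mol/L
    species: str = "imine"  # "amine" | "imine"
    x0: float | None = None  # mol/L
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concentration = np.asarray(self.concentration, dtype=float)
        if self.times.shape != self.concentration.shape:
            raise ValueError("times and concentration must have equal length")
        if not _strictly_increasing(self.times):
            raise ValueError("times must be strictly increasing")
        # background-corrected absorbance traces reuse this container and may
        # legitimately dip below zero; molar concentrations may not
        if self.species != "absorbance" and np.any(self.concentration < 0):
            raise ValueError("concentrations must be nonnegative")

    def __len__(self) -> int:
        return self.times.size

    @classmethod
    def from_csv(cls, path, species: str = "amine", x0: float | None = None,
                 **metadata) -> "ConcentrationTrace":
        df = pd.read_csv(path)
        scale = {"concentration_M": 1.0, "concentration_mM": 1e-3,
                 "concentration_uM": 1e-6}
        col = next((c for c in scale if c in df.columns), None)
        if col is None:
            raise ValueError(
                "CSV needs a concentration_M / concentration_mM / concentration_uM column"
            )
        return cls(times=df["time_s"].to_numpy(),
                   concentration=df[col].to_numpy() * scale[col],
                   species=species, x0=x0, metadata=metadata)

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.times, "concentration_M": self.concentration}
                     ).to_csv(path, index=False)


@dataclass
class AbsorptivityCalibration:
    """Beer-Lambert calibration: epsilon is the slope of A vs c*l."""

    epsilon: float  # L/mol/cm
    detection_wavelength: float | None  # nm
    path_length: float  # cm
    fit_r2: float
    calibration_points: list[tuple[float, float]]  # (mol/L, a.u.)
    intercept: float = 0.0
    intercept_stderr: float = float("nan")
    valid: bool = True

    def __post_init__(self) -> None:
        if len(self.calibration_points) < 2:
            raise ValueError("need at least 2 calibration points")
        if not (0.0 <= self.fit_r2 <= 1.0 + 1e-12):
            raise ValueError("fit_r2 must lie in [0, 1]")
        if self.epsilon <= 0:
            self.valid = False


@dataclass
class FormulationSpec:
    """Macromer formulation: mass m dissolved in volume V, with a fraction
    D_f of repeat units (molar mass M_Unit) carrying the reactive aldehyde."""

    macromer_mass: float  # g
    degree_of_functionalization: float  # fraction
    unit_molar_mass: float = 198.0  # g/mol
    volume: float = 1.0  # L
    weight_percent: float | None = None  # optional, redundant

    def __post_init__(self) -> None:
        if self.macromer_mass < 0 or self.unit_molar_mass <= 0 or self.volume <= 0:
            raise ValueError("mass, unit molar mass and volume must be positive")
        if not (0.0 <= self.degree_of_functionalization <= 1.0):
            raise ValueError("degree of functionalization must be in (0, 1]")


def preprocess_uvvis_series(series: SpectralSeries,
                            detection_wavelength: float) -> ConcentrationTrace:
    """Background-correct a spectral series at one detection wavelength.

    The first spectrum is subtracted from all spectra, so the returned trace
    is zero at t0 and tracks the *change* in absorbance (the evolving imine
    signal). The wavelength is snapped to the nearest grid point, never
    interpolated; the chosen grid value is recorded in metadata.

    Returns a trace whose "concentration" field still holds absorbance
    (a.u.); feed it to :func:`absorbance_to_concentration`.
    """
    wl = series.wavelengths
    if not (wl[0] <= detection_wavelength <= wl[-1]):
        raise ValueError(
            f"detection wavelength {detection_wavelength} nm outside the "
            f"measured range [{wl[0]}, {wl[-1]}] nm"
        )
    if series.times.size < 2:
        raise ValueError("need at least 2 spectra to background-correct")
    idx = int(np.argmin(np.abs(wl - detection_wavelength)))
    chosen = float(wl[idx])
    logger.info("detection wavelength %.4g nm -> nearest grid point %.4g nm",
                detection_wavelength, chosen)
    trace = series.absorbance[:, idx] - series.absorbance[0, idx]
    return ConcentrationTrace(
        times=series.times.copy(), concentration=trace, species="absorbance",
        metadata={**series.metadata,
                  "detection_wavelength_nm": chosen,
                  "requested_wavelength_nm": float(detection_wavelength),
                  "path_length_cm": series.path_length,
                  "units": "a.u."})


def fit_molar_absorptivity(points: Sequence[tuple[float, float]],
                           path_length: float = 1.0,
                           detection_wavelength: float | None = None,
                           ) -> AbsorptivityCalibration:
    """Ordinary least-squares Beer-Lambert fit: epsilon = slope of A vs c*l.

    The intercept is estimated (not forced through the origin) and reported;
    a warning is raised when it is significant (> 3x its standard error).
    """
    pts = [(float(c), float(a)) for c, a in points]
    if len(pts) < 2:
        raise ValueError("need at least 2 calibration points")
    c = np.array([p[0] for p in pts])
    a = np.array([p[1] for p in pts])
    if np.any(c < 0):
        raise ValueError("concentrations must be nonnegative")
    if np.allclose(c, c[0]):
        raise ValueError("degenerate calibration: all concentrations equal")
    res = stats.linregress(c * path_length, a)
    r2 = float(res.rvalue ** 2) if np.isfinite(res.rvalue) else 0.0
    epsilon = float(res.slope)
    if np.isfinite(res.intercept_stderr) and res.intercept_stderr > 0 and \
            abs(res.intercept) > 3 * res.intercept_stderr:
        warnings.warn(
            f"calibration intercept {res.intercept:.3g} exceeds 3x its standard "
            f"error ({res.intercept_stderr:.3g}); check the blank correction",
            stacklevel=2,
        )
    return AbsorptivityCalibration(
        epsilon=epsilon,
        detection_wavelength=detection_wavelength,
        path_length=float(path_length),
        fit_r2=r2,
        calibration_points=pts,
        intercept=float(res.intercept),
        intercept_stderr=float(res.intercept_stderr),
    )


def absorbance_to_concentration(trace: ConcentrationTrace,
                                calibration: AbsorptivityCalibration,
                                ) -> ConcentrationTrace:
    """Invert Beer-Lambert: c(t) = A(t) / (epsilon * l).

    Negative values (noise around the baseline) are clipped to zero; the
    number of clipped points is logged and recorded in metadata.
    """
    if calibration.epsilon <= 0:
        raise ValueError("calibration epsilon must be positive")
    c = np.asarray(trace.concentration, dtype=float) / (
        calibration.epsilon * calibration.path_length)
    n_clipped = int(np.sum(c < 0))
    if n_clipped:
        logger.info("clipped %d negative concentration points to 0", n_clipped)
    c = np.clip(c, 0.0, None)
    return ConcentrationTrace(
        times=trace.times.copy(), concentration=c, species="imine",
        x0=trace.x0,
        metadata={**trace.metadata, "n_clipped_negative": n_clipped,
                  "epsilon_L_mol_cm": calibration.epsilon, "units": "mol/L"},
    )


def amine_consumption_trace(imine: ConcentrationTrace, x0: float,
                            tolerance: float = 0.05) -> ConcentrationTrace:
    """Convert an imine-formation trace to amine consumption: x(t) = x0 - [Im](t).

    The kinetic model fits the disappearance of the amine, while UV-vis
    measures the appearing imine; with equimolar mixing each imine consumes
    one amine. Values are clipped to [0, x0]; overshoot beyond
    ``tolerance * x0`` triggers a warning (it indicates a bad x0 or epsilon).
    """
    if x0 <= 0:
        raise ValueError("x0 must be positive")
    im = np.asarray(imine.concentration, dtype=float)
    overshoot = im - x0
    if np.any(overshoot > tolerance * x0):
        warnings.warn(
            f"imine concentration exceeds x0={x0:.3g} M by more than "
            f"{tolerance:.0%}; check epsilon / x0", stacklevel=2)
    x = np.clip(x0 - im, 0.0, x0)
    return ConcentrationTrace(
        times=imine.times.copy(), concentration=x, species="amine", x0=float(x0),
        metadata={**imine.metadata, "units": "mol/L"},
    )


def schiff_standard_concentrations(
        stock_concentrations: Sequence[float],
        dilution_steps: Sequence[tuple[float, float]],
) -> np.ndarray:
    """Serial-dilution bookkeeping for a standard series.

    Each step is (aliquot_volume, final_total_volume) in consistent units;
    the concentration after a step is multiplied by aliquot/total. E.g. the
    Schiff-test scheme — 500 uL standard + 2500 uL reagent, then a 100 uL
    aliquot diluted to 1000 uL — is ``[(500, 3000), (100, 1000)]``.
    """
    stocks = np.asarray(stock_concentrations, dtype=float)
    if np.any(stocks < 0):
        raise ValueError("stock concentrations must be nonnegative")
    factor = 1.0
    for aliquot, total in dilution_steps:
        if aliquot <= 0 or total <= 0:
            raise ValueError("volumes must be positive")
        if aliquot > total:
            raise ValueError(
                f"aliquot {aliquot} exceeds the final volume {total}")
        factor *= aliquot / total
    return stocks * factor


def degree_of_oxidation(measured_aldehyde: float,
                        uronic_unit_concentration: float) -> float:
    """DOx = [CHO] / (2 * [uronic unit]).

    Each oxidized uronic-acid unit carries two aldehyde functions, so the
    fraction of oxidized units is half the aldehyde-per-unit ratio. Returned
    as a fraction (0.10 == 10%).
    """
    if measured_aldehyde < 0 or uronic_unit_concentration <= 0:
        raise ValueError("concentrations must be positive")
    dox = measured_aldehyde / (2.0 * uronic_unit_concentration)
    if dox > 1.0:
        raise ValueError(
            f"DOx = {dox:.3g} > 1: inconsistent aldehyde/unit concentrations")
    return dox


def macromer_aldehyde_concentration(spec: FormulationSpec) -> float:
    """Aldehyde-function concentration of a macromer solution (mol/L).

    c = (m / (M_Unit * V)) * D_f — one reactive aldehyde equivalent per
    functionalized repeat unit. (The Schiff-test DOx convention of two
    aldehydes per oxidized unit applies to counting oxidized units, not to
    the reactive-equivalent concentration used for kinetics; both
    conventions are explicit in this module.)
    """
    return (spec.macromer_mass / (spec.unit_molar_mass * spec.volume)) \
        * spec.degree_of_functionalization
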