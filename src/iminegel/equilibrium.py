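"""Cross-link equilibria of dynamic imine hydrogels.

Single-amine systems: with aldehyde functions at [Ald]0 and amine
functions at [Am]0 = chi_Am * [Ald]0, the equilibrium imine concentration
is the smaller root of the binding quadratic

    x^2 - ([Ald]0 + [Am]0 + 1/Keq) x + [Ald]0 [Am]0 = 0.

An aldehyde is counted as *cross-linked* when it is bound to an arm of a
bifunctional amine whose sibling arm is also bound; assuming the two arms
bind independently, the ideal maximum cross-linked aldehyde fraction is

    chi_XL = ([Im]/[Ald]0) * ([Im]/[Am]0).

Competitive two-amine systems use the exact two-competing-ligand
solution: free aldehyde [Ald] is the unique root in [0, [Ald]0] of the
mass-balance cubic built from the dissociation constants K_Ai = 1/Keq_i,
and each imine follows [Im_i] = [A_i]0 [Ald] / (K_Ai + [Ald]). Summing
the per-amine chi_XL contributions yields the total cross-linked
fraction; the difference surface between a (0.5 + 0.5)-equivalent mixed
system and the 0.5-equivalent single-amine baseline exposes the
competitive-softening regime, where adding a weaker cross-linker
*removes* cross-links.

All public interfaces take association constants Keq (L/mol) and convert
to dissociation constants internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BindingSystem",
    "CompetitiveSystem",
    "EquilibriumState",
    "CrosslinkSurface",
    "single_ligand_equilibrium",
    "crosslinked_fraction",
    "fraction_vs_ratio_curve",
    "competitive_equilibrium",
    "total_crosslinked_fraction",
    "softening_map",
    "per_amine_crosslink_index",
    "bound_fraction_isotherm",
    "concentration_sweep_isotherm",
    "register_isotherm_model",
    "correlate_descriptor_vs_log_rec",
    "load_dft_descriptors",
    "load_rec_table",
    "load_rec_uvvis_vs_nmr",
]

MASS_BALANCE_RTOL = 1e-10


@dataclass
class BindingSystem:
    """One aldehyde + one amine at ratio chi_am = [Am]0/[Ald]0."""

    ald0: float  # mol/L, aldehyde-function concentration
    chi_am: float  # dimensionless amine/aldehyde ratio
    Keq: float  # L/mol

    def __post_init__(self) -> None:
        if self.ald0 <= 0:
            raise ValueError("ald0 must be positive")
        if self.chi_am < 0 or self.Keq < 0:
            raise ValueError("chi_am and Keq must be nonnegative")

    @property
    def am0(self) -> float:
        return self.chi_am * self.ald0


@dataclass
class CompetitiveSystem:
    """One aldehyde + two amines, parameterized by dissociation constants.

    Use :meth:`from_keq` to build from association constants. The total
    amine ratio is capped at 1 by default (beyond saturation the hydrogel
    softens trivially via singly bound pendants); pass
    ``allow_excess=True`` to override.
    """

    ald0: float  # mol/L
    a1_0: float  # mol/L, amine-function concentration of A1
    a2_0: float  # mol/L
    K_A1: float  # mol/L, dissociation constant (1/Keq)
    K_A2: float  # mol/L
    allow_excess: bool = False

    def __post_init__(self) -> None:
        if self.ald0 <= 0:
            raise ValueError("ald0 must be positive")
        for v in (self.a1_0, self.a2_0, self.K_A1, self.K_A2):
            if v < 0:
                raise ValueError("concentrations and constants must be nonnegative")
        chi_total = (self.a1_0 + self.a2_0) / self.ald0
        if chi_total > 1.0 + 1e-12 and not self.allow_excess:
            raise ValueError(
                f"total amine ratio {chi_total:.3g} exceeds 1 (aldehyde "
                "saturation); pass allow_excess=True to override")

    @classmethod
    def from_keq(cls, ald0: float, a1_0: float, a2_0: float, Keq1: float,
                 Keq2: float, allow_excess: bool = False) -> "CompetitiveSystem":
        if Keq1 <= 0 or Keq2 <= 0:
            raise ValueError("Keq values must be positive (use a1_0/a2_0 = 0 "
                             "for an absent amine)")
        return cls(ald0=ald0, a1_0=a1_0, a2_0=a2_0, K_A1=1.0 / Keq1,
                   K_A2=1.0 / Keq2, allow_excess=allow_excess)


@dataclass
class EquilibriumState:
    """Equilibrated concentrations of a competitive system (mol/L)."""

    ald_free: float
    im1: float
    im2: float
    a1_free: float
    a2_free: float

    def check_mass_balance(self, system: CompetitiveSystem,
                           rtol: float = MASS_BALANCE_RTOL) -> None:
        scale = system.ald0
        for lhs, rhs in (
                (self.ald_free + self.im1 + self.im2, system.ald0),
                (self.a1_free + self.im1, system.a1_0),
                (self.a2_free + self.im2, system.a2_0)):
            if abs(lhs - rhs) > rtol * max(scale, rhs):
                raise AssertionError(
                    f"mass balance violated: {lhs} != {rhs}")
        if min(self.ald_free, self.im1, self.im2, self.a1_free,
               self.a2_free) < -rtol * scale:
            raise AssertionError("negative equilibrium concentration")


@dataclass
class CrosslinkSurface:
    """chi_XL (or delta chi_XL) tabulated over one or two labelled axes."""

    axis1: np.ndarray
    axis2: np.ndarray | None
    values: np.ndarray
    axis1_label: str = ""
    axis2_label: str = ""
    value_label: str = "chi_XL"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.axis1 = np.asarray(self.axis1, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.axis2 is not None:
            self.axis2 = np.asarray(self.axis2, dtype=float)
            expected = (self.axis1.size, self.axis2.size)
        else:
            expected = (self.axis1.size,)
        if self.values.shape != expected:
            raise ValueError(f"values shape {self.values.shape} != {expected}")
        if np.any(np.abs(self.values) > 1.0 + 1e-9):
            raise ValueError("cross-link fractions must lie in [-1, 1]")

    def to_dataframe(self) -> pd.DataFrame:
        if self.axis2 is None:
            return pd.DataFrame({self.axis1_label or "axis1": self.axis1,
                                 self.value_label: self.values})
        a1, a2 = np.meshgrid(self.axis1, self.axis2, indexing="ij")
        return pd.DataFrame({
            self.axis1_label or "axis1": a1.ravel(),
            self.axis2_label or "axis2": a2.ravel(),
            self.value_label: self.values.ravel()})


def single_ligand_equilibrium(ald0: float, am0: float, Keq: float) -> float:
    """Equilibrium imine concentration for one aldehyde + one amine.

    Smaller root of x^2 - (ald0 + am0 + 1/Keq) x + ald0 am0 = 0, computed
    in the cancellation-free form 2 ald0 am0 / (b + sqrt(b^2 - 4 ald0 am0)).
    """
    if ald0 < 0 or am0 < 0 or Keq < 0:
        raise ValueError("inputs must be nonnegative")
    if Keq == 0.0 or am0 == 0.0 or ald0 == 0.0:
        return 0.0
    if np.isinf(Keq):
        return min(ald0, am0)
    b = ald0 + am0 + 1.0 / Keq
    disc = b * b - 4.0 * ald0 * am0
    return 2.0 * ald0 * am0 / (b + np.sqrt(disc))


def crosslinked_fraction(system: BindingSystem) -> float:
    """Ideal maximum cross-linked aldehyde fraction chi_XL for one amine."""
    if system.chi_am == 0.0 or system.Keq == 0.0:
        return 0.0
    am0 = system.am0
    im = single_ligand_equilibrium(system.ald0, am0, system.Keq)
    return (im / system.ald0) * (im / am0)


def fraction_vs_ratio_curve(Keq: float, ald0: float,
                            chi_grid: np.ndarray | None = None,
                            ) -> CrosslinkSurface:
    """chi_XL as a function of the amine ratio chi_Am at fixed Keq.

    The default grid spans 0 to 1.4 equivalents. For strong binders the
    curve peaks at chi_Am <= 1 and drops beyond it: past saturation every
    extra amine converts a bridge into two singly bound pendants.
    """
    if chi_grid is None:
        chi_grid = np.linspace(0.0, 1.4, 141)
    chi_grid = np.asarray(chi_grid, dtype=float)
    if np.any(chi_grid < 0) or np.any(chi_grid > 2.0):
        raise ValueError("chi grid must lie within [0, 2]")
    values = np.array([
        crosslinked_fraction(BindingSystem(ald0=ald0, chi_am=c, Keq=Keq))
        for c in chi_grid])
    return CrosslinkSurface(axis1=chi_grid, axis2=None, values=values,
                            axis1_label="chi_Am",
                            metadata={"ald0_M": ald0, "Keq_L_mol": Keq})


def _mass_balance(x: float, system: CompetitiveSystem) -> float:
    """f([Ald]) = [Ald] + sum_i [A_i]0 [Ald]/(K_i + [Ald]) - [Ald]0;
    strictly increasing on [0, ald0] with a unique root."""
    total = x - system.ald0
    for a0, k in ((system.a1_0, system.K_A1), (system.a2_0, system.K_A2)):
        if a0 > 0:
            total += a0 * x / (k + x)
    return total


def _cubic_real_roots(a2: float, a1: float, a0: float) -> np.ndarray:
    """Real roots of x^3 + a2 x^2 + a1 x + a0, via the trigonometric form
    when all three roots are real (the generic case here) and Cardano
    otherwise."""
    p = a1 - a2 * a2 / 3.0
    q = 2.0 * a2 ** 3 / 27.0 - a2 * a1 / 3.0 + a0
    shift = -a2 / 3.0
    disc = (q / 2.0) ** 2 + (p / 3.0) ** 3
    if disc <= 0 and p < 0:
        m = 2.0 * np.sqrt(-p / 3.0)
        arg = np.clip(3.0 * q / (p * m), -1.0, 1.0)
        theta = np.arccos(arg) / 3.0
        return shift + m * np.cos(theta - 2.0 * np.pi * np.arange(3) / 3.0)
    # one real root
    s = np.sqrt(disc)
    u = np.cbrt(-q / 2.0 + s)
    v = np.cbrt(-q / 2.0 - s)
    return np.array([shift + u + v])


def competitive_equilibrium(system: CompetitiveSystem) -> EquilibriumState:
    """Exact equilibrium of one aldehyde competed for by two amines.

    Solves the mass-balance cubic in free aldehyde, selects the unique root
    in [0, [Ald]0], then applies Newton polishing on the monotone
    mass-balance function; falls back to numpy's polynomial roots if the
    closed form misses. Mass balances are asserted to 1e-10 relative.
    """
    ald0 = system.ald0
    # degenerate single-ligand and no-ligand cases bypass the cubic
    active = [(a0, k) for a0, k in
              ((system.a1_0, system.K_A1), (system.a2_0, system.K_A2)) if a0 > 0]
    if len(active) < 2:
        if not active:
            state = EquilibriumState(ald0, 0.0, 0.0, 0.0, 0.0)
        else:
            a0, k = active[0]
            im = single_ligand_equilibrium(ald0, a0, 1.0 / k)
            free = ald0 - im
            if system.a1_0 > 0:
                state = EquilibriumState(free, im, 0.0, system.a1_0 - im, 0.0)
            else:
                state = EquilibriumState(free, 0.0, im, 0.0, system.a2_0 - im)
        state.check_mass_balance(system)
        return state

    k1d, k2d = system.K_A1, system.K_A2
    a10, a20 = system.a1_0, system.a2_0
    a2c = k1d + k2d + a10 + a20 - ald0
    a1c = k1d * k2d + k2d * (a10 - ald0) + k1d * (a20 - ald0)
    a0c = -k1d * k2d * ald0
    roots = _cubic_real_roots(a2c, a1c, a0c)
    tol = 1e-9 * ald0
    candidates = roots[(roots >= -tol) & (roots <= ald0 + tol)]
    if candidates.size == 0:
        roots = np.roots([1.0, a2c, a1c, a0c])
        roots = roots[np.abs(roots.imag) < 1e-9 * max(1.0, ald0)].real
        candidates = roots[(roots >= -tol) & (roots <= ald0 + tol)]
    if candidates.size == 0:
        raise RuntimeError(
            f"no physically valid root in [0, {ald0:.3g}]; roots = {roots}")
    x = float(np.clip(candidates[np.argmin(np.abs(
        [_mass_balance(c, system) for c in candidates]))], 0.0, ald0))
    # Newton polish on the monotone mass balance
    for _ in range(50):
        f = _mass_balance(x, system)
        df = 1.0 + a10 * k1d / (k1d + x) ** 2 + a20 * k2d / (k2d + x) ** 2
        step = f / df
        x_new = float(np.clip(x - step, 0.0, ald0))
        if abs(x_new - x) <= 1e-16 * max(x, ald0 * 1e-12):
            x = x_new
            break
        x = x_new
    im1 = a10 * x / (k1d + x)
    im2 = a20 * x / (k2d + x)
    state = EquilibriumState(ald_free=x, im1=im1, im2=im2,
                             a1_free=a10 - im1, a2_free=a20 - im2)
    state.check_mass_balance(system)
    return state


def total_crosslinked_fraction(state: EquilibriumState,
                               system: CompetitiveSystem) -> float:
    """Total chi_XL of a competitive system: per-amine chi contributions
    (im_i/[Ald]0)(im_i/[A_i]0) summed over amines."""
    total = 0.0
    for im, a0 in ((state.im1, system.a1_0), (state.im2, system.a2_0)):
        if a0 > 0:
            total += (im / system.ald0) * (im / a0)
    if not -1e-9 <= total <= 1.0 + 1e-9:
        raise AssertionError(f"chi_XL out of range: {total}")
    return float(np.clip(total, 0.0, 1.0))


def _mixed_chi(K1: float, K2: float, chi1: float, chi2: float,
               ald0: float) -> float:
    sys2 = CompetitiveSystem.from_keq(ald0, chi1 * ald0, chi2 * ald0, K1, K2)
    return total_crosslinked_fraction(competitive_equilibrium(sys2), sys2)


def _delta_chi(K1: float, K2: float, chi1: float, chi2: float,
               ald0: float) -> float:
    baseline = crosslinked_fraction(BindingSystem(ald0=ald0, chi_am=chi1,
                                                  Keq=K1))
    return _mixed_chi(K1, K2, chi1, chi2, ald0) - baseline


def softening_map(Keq1_grid: np.ndarray | None = None,
                  Keq2_grid: np.ndarray | None = None,
                  chi1: float = 0.5, chi2: float = 0.5,
                  ald0: float = 10.1e-3,
                  refine: bool = True) -> tuple[CrosslinkSurface, dict]:
    """Delta chi_XL surface for adding chi2 equivalents of competitor A2 to
    a gel holding chi1 equivalents of A1.

    Returns the surface over (Keq1, Keq2) and a report locating the most
    negative Delta chi (maximal softening), refined by local 10x regridding
    to two significant figures in each Keq. Negative cells are the
    softening regime: the competitor steals aldehydes from A1 without
    contributing enough cross-links of its own.
    """
    if Keq1_grid is None:
        Keq1_grid = np.logspace(1, 7, 121)
    if Keq2_grid is None:
        Keq2_grid = np.logspace(1, 7, 121)
    Keq1_grid = np.asarray(Keq1_grid, dtype=float)
    Keq2_grid = np.asarray(Keq2_grid, dtype=float)
    if Keq1_grid.size == 0 or Keq2_grid.size == 0:
        raise ValueError("Keq grids must be nonempty")

    values = np.empty((Keq1_grid.size, Keq2_grid.size))
    for i, K1 in enumerate(Keq1_grid):
        baseline = crosslinked_fraction(BindingSystem(ald0=ald0, chi_am=chi1,
                                                      Keq=K1))
        for j, K2 in enumerate(Keq2_grid):
            values[i, j] = _mixed_chi(K1, K2, chi1, chi2, ald0) - baseline
    surface = CrosslinkSurface(
        axis1=Keq1_grid, axis2=Keq2_grid, values=values,
        axis1_label="Keq_A1", axis2_label="Keq_A2",
        value_label="delta_chi_XL",
        metadata={"ald0_M": ald0, "chi1": chi1, "chi2": chi2})

    i, j = np.unravel_index(np.argmin(values), values.shape)
    K1_best, K2_best = float(Keq1_grid[i]), float(Keq2_grid[j])
    delta_best = float(values[i, j])
    if refine:
        # local 10x regridding around the coarse argmin, iterated until the
        # location is stable to two significant figures
        span1 = np.log10(Keq1_grid[min(i + 1, Keq1_grid.size - 1)]) - \
            np.log10(Keq1_grid[max(i - 1, 0)])
        span2 = np.log10(Keq2_grid[min(j + 1, Keq2_grid.size - 1)]) - \
            np.log10(Keq2_grid[max(j - 1, 0)])
        for _ in range(4):
            g1 = np.logspace(np.log10(K1_best) - span1, np.log10(K1_best) + span1, 21)
            g2 = np.logspace(np.log10(K2_best) - span2, np.log10(K2_best) + span2, 21)
            local = np.empty((g1.size, g2.size))
            for ii, K1 in enumerate(g1):
                for jj, K2 in enumerate(g2):
                    local[ii, jj] = _delta_chi(K1, K2, chi1, chi2, ald0)
            ii, jj = np.unravel_index(np.argmin(local), local.shape)
            K1_best, K2_best = float(g1[ii]), float(g2[jj])
            delta_best = float(local[ii, jj])
            span1 /= 10.0
            span2 /= 10.0
    report = {
        "Keq_A1_max_softening": _round_sig(K1_best, 2),
        "Keq_A2_max_softening": _round_sig(K2_best, 2),
        "delta_chi_min": delta_best,
        "n_negative_cells": int(np.sum(values < 0)),
    }
    return surface, report


def _round_sig(x: float, sig: int) -> float:
    if x == 0:
        return 0.0
    return float(round(x, -int(np.floor(np.log10(abs(x)))) + (sig - 1)))


def per_amine_crosslink_index(imine_concs, initial_concs) -> float:
    """Sum of squared per-amine bound fractions, sum_i (im_i / a_i0)^2.

    An imine from one amine cannot cross-link with an imine from another,
    so total imine concentration overstates connectivity in mixed systems;
    squaring each amine's bound fraction counts only doubly bound
    (bridging) cross-linkers. Used to compare formulations as a relative
    change.
    """
    total = 0.0
    for im, a0 in zip(imine_concs, initial_concs, strict=True):
        if a0 == 0:
            if im > 0:
                raise ValueError("nonzero imine with zero initial amine")
            continue
        if im > a0 * (1 + 1e-9):
            raise ValueError(f"imine {im} exceeds initial amine {a0}")
        total += (im / a0) ** 2
    return total


# --- bound-fraction isotherms -------------------------------------------------

def _analytic_isotherm(x0: float, keq: np.ndarray) -> np.ndarray:
    return np.array([single_ligand_equilibrium(x0, x0, k) / x0 for k in keq])


_ISOTHERM_MODELS = {"analytic": _analytic_isotherm}


def register_isotherm_model(name: str, fn) -> None:
    """Register an alternative bound-fraction model fn(x0, keq_array) ->
    fraction array (e.g. a Bell-model or Poisson treatment)."""
    _ISOTHERM_MODELS[name] = fn


def bound_fraction_isotherm(x0: float, Keq_grid: np.ndarray | None = None,
                            model: str = "analytic") -> CrosslinkSurface:
    """Equilibrium bound fraction [Im]/[X]0 vs Keq for equimolar reactive
    groups at concentration x0. Changing x0 shifts the isotherm along the
    log-Keq axis without changing its shape."""
    if x0 <= 0:
        raise ValueError("x0 must be positive")
    if Keq_grid is None:
        Keq_grid = np.logspace(-1, 7, 161)
    Keq_grid = np.asarray(Keq_grid, dtype=float)
    if model not in _ISOTHERM_MODELS:
        raise ValueError(
            f"unknown isotherm model {model!r}; registered models: "
            f"{sorted(_ISOTHERM_MODELS)}")
    values = _ISOTHERM_MODELS[model](x0, Keq_grid)
    return CrosslinkSurface(axis1=Keq_grid, axis2=None, values=values,
                            axis1_label="Keq_L_mol",
                            value_label="bound_fraction",
                            metadata={"x0_M": x0, "model": model})


def concentration_sweep_isotherm(Keq: float,
                                 x0_grid: np.ndarray | None = None,
                                 model: str = "analytic") -> CrosslinkSurface:
    """Bound fraction vs reactive-group concentration at fixed Keq."""
    if x0_grid is None:
        x0_grid = np.logspace(-5, 0, 101)
    x0_grid = np.asarray(x0_grid, dtype=float)
    if np.any(x0_grid <= 0):
        raise ValueError("x0 grid must be positive")
    if model not in _ISOTHERM_MODELS:
        raise ValueError(
            f"unknown isotherm model {model!r}; registered models: "
            f"{sorted(_ISOTHERM_MODELS)}")
    fn = _ISOTHERM_MODELS[model]
    values = np.array([fn(x0, np.array([Keq]))[0] for x0 in x0_grid])
    return CrosslinkSurface(axis1=x0_grid, axis2=None, values=values,
                            axis1_label="x0_M", value_label="bound_fraction",
                            metadata={"Keq_L_mol": Keq, "model": model})


# --- descriptor/REC correlation ----------------------------------------------

def correlate_descriptor_vs_log_rec(descriptor: pd.Series,
                                    recs: pd.Series) -> dict:
    """OLS of a dimensionless free-energy descriptor against log10 of a
    rate/equilibrium constant, paired by amine identity.

    Both inputs are indexed by amine label; ``recs`` must already be
    log10-transformed. Returns slope, intercept and r^2.
    """
    common = descriptor.index.intersection(recs.index)
    dropped = set(descriptor.index).symmetric_difference(recs.index)
    if len(common) < 3:
        raise ValueError(
            f"need >= 3 paired points; common amines: {list(common)}, "
            f"unmatched: {sorted(dropped)}")
    x = descriptor.loc[common].astype(float).to_numpy()
    y = recs.loc[common].astype(float).to_numpy()
    res = stats.linregress(x, y)
    return {"slope": float(res.slope), "intercept": float(res.intercept),
            "r2": float(res.rvalue ** 2), "n": int(len(common))}


# --- packaged fixtures --------------------------------------------------------

R_KCAL = 1.9872041e-3  # kcal/mol/K
STANDARD_T = 298.15  # K, temperature of the free-energy calculations


def _read_packaged(name: str) -> pd.DataFrame:
    with resources.files("iminegel.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_dft_descriptors(dimensionless: bool = True) -> pd.DataFrame:
    """Computed per-amine descriptors: nucleophilicity, natural charge and
    the free energies of tetrahedral-intermediate formation (dG1*),
    breakdown (dG2*) and overall reaction (drG0). With
    ``dimensionless=True`` the energies are divided by RT at 298.15 K."""
    df = _read_packaged("dft_descriptors.tsv").set_index("amine")
    if dimensionless:
        rt = R_KCAL * STANDARD_T
        for col in ("dG1_kcal_mol", "dG2_kcal_mol", "drG_kcal_mol"):
            df[col.replace("_kcal_mol", "_over_RT")] = df[col] / rt
    return df


def load_rec_table() -> pd.DataFrame:
    """Measured rate/equilibrium constants for the aldehyde (1-3) x amine
    (4-9) series (SI units: L/mol/s, 1/s, L/mol)."""
    return _read_packaged("rec_table.tsv")


def load_rec_uvvis_vs_nmr() -> pd.DataFrame:
    """UV-vis vs NMR method-comparison constants for the oxidized-alginate
    pairs (2+5 oxime, 2+7 hydrazone)."""
    return _read_packaged("rec_uvvis_vs_nmr.tsv")
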