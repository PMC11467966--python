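"""Reversible second-order equimolar kinetics of imine formation.

The central model: an amine and an aldehyde mixed at equal initial
concentration x0 condense reversibly,

    dx/dt = -k1 * x**2 + k_minus1 * (x0 - x),        x(0) = x0,

where x(t) is the remaining amine concentration, k1 (L mol^-1 s^-1) the
forward rate constant and k_minus1 (s^-1) the hydrolysis rate constant.
The equilibrium constant is Keq = k1 / k_minus1 (L mol^-1). Fitting a
measured amine-consumption trace to the closed-form solution yields all
three constants simultaneously — no pseudo-first-order approximation and
no separate titration for Keq.

The rate polynomial -k1 x^2 - k_minus1 x + k_minus1 x0 has one root
x_eq in (0, x0] (the equilibrium amine concentration) and one negative
root r; separating variables gives

    x(t) = (x_eq - r * w * exp(-q t)) / (1 - w * exp(-q t)),

with q = k1 * (x_eq - r) and w = (x0 - x_eq) / (x0 - r). The module also
provides the irreversible limit x(t) = x0 / (1 + k1 x0 t), used to
constrain fits when k_minus1 is too small to resolve on the experimental
time scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np

from .spectro import ConcentrationTrace

__all__ = [
    "RateConstants",
    "FitResult",
    "reversible_equimolar_solution",
    "irreversible_second_order_solution",
    "equilibrium_amine",
    "fit_reversible",
    "fit_irreversible",
    "fit_constrained_reversible",
    "fit_auto",
    "aggregate_replicates",
]

_KM1_LOWER_BOUND = 1e-12  # s^-1, optimizer lower bound for the reverse rate
# a fitted reverse conversion k_minus1 * span below this is indistinguishable
# from an irreversible reaction on the experimental time scale
_REVERSIBILITY_RESOLUTION = 1e-3


def _unresolvable_reverse(km1: float, times: np.ndarray) -> bool:
    span = float(times[-1] - times[0]) if len(times) > 1 else 0.0
    return km1 <= 2 * _KM1_LOWER_BOUND or km1 * span < _REVERSIBILITY_RESOLUTION


@dataclass
class RateConstants:
    """The (k1, k_minus1, Keq) triple with uncertainties and provenance."""

    k1: float  # L/mol/s
    k_minus1: float  # 1/s
    Keq: float  # L/mol
    k1_uncertainty: float = float("nan")
    k_minus1_uncertainty: float = float("nan")
    Keq_uncertainty: float = float("nan")
    method: str = "free_fit"  # free_fit | constrained_fit | irreversible_fit
    aggregation: str = "per_replicate_mean"
    n_replicates: int = 1

    def __post_init__(self) -> None:
        if (np.isfinite(self.k1) and self.k1 < 0) or (
                np.isfinite(self.k_minus1) and self.k_minus1 < 0):
            raise ValueError("rate constants must be nonnegative")


@dataclass
class FitResult:
    """Carrier for a single nonlinear least-squares kinetic fit."""

    parameters: RateConstants
    standard_errors: dict
    residuals: np.ndarray  # mol/L, model - data
    sum_squared_error: float
    converged: bool
    fixed_parameters: list = field(default_factory=list)
    flags: list = field(default_factory=list)
    x0: float | None = None
    covariance: np.ndarray | None = None


def _validate_rates(k1: float, k_minus1: float, x0: float) -> None:
    if k1 < 0 or k_minus1 < 0:
        raise ValueError("rate constants must be nonnegative")
    if x0 <= 0:
        raise ValueError("x0 must be positive")


def equilibrium_amine(k1: float, k_minus1: float, x0: float) -> float:
    """Equilibrium amine concentration: positive root of
    k1 x^2 + k_minus1 x - k_minus1 x0 = 0."""
    _validate_rates(k1, k_minus1, x0)
    if k1 == 0.0:
        return x0
    if k_minus1 == 0.0:
        return 0.0
    disc = k_minus1 * k_minus1 + 4.0 * k1 * k_minus1 * x0
    # stable form: 2c / (-b - sqrt(disc)) avoids cancellation for small k_minus1
    return 2.0 * k_minus1 * x0 / (k_minus1 + np.sqrt(disc))


def irreversible_second_order_solution(t, k1: float, x0: float):
    """x(t) = x0 / (1 + k1 x0 t): second-order decay with no back-reaction."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be nonnegative")
    _validate_rates(k1, 0.0, x0)
    return x0 / (1.0 + k1 * x0 * t)


def reversible_equimolar_solution(t, k1: float, k_minus1: float, x0: float):
    """Closed-form amine concentration x(t) for the reversible equimolar model.

    Monotone nonincreasing from x(0) = x0 to the equilibrium value
    ``equilibrium_amine(k1, k_minus1, x0)``. k1 = k_minus1 = 0 returns the
    constant x0 (no reaction).
    """
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    if np.any(t < 0):
        raise ValueError("t must be nonnegative")
    _validate_rates(k1, k_minus1, x0)
    if k1 == 0.0:
        x = np.full_like(t, x0)
    elif k_minus1 == 0.0:
        x = irreversible_second_order_solution(t, k1, x0)
    else:
        xeq = equilibrium_amine(k1, k_minus1, x0)
        disc = k_minus1 * k_minus1 + 4.0 * k1 * k_minus1 * x0
        r = -(k_minus1 + np.sqrt(disc)) / (2.0 * k1)  # negative root
        delta = np.sqrt(disc) / k1  # xeq - r, exact
        q = np.sqrt(disc)  # k1 * (xeq - r)
        w = (x0 - xeq) / (x0 - r)
        # cancellation-free rearrangement: the naive (xeq - r w e)/(1 - w e)
        # loses all digits when q*t and (1 - w) are both tiny (the
        # near-irreversible regime); write the denominator as a sum of
        # positive terms instead
        with np.errstate(under="ignore"):
            e = np.exp(-q * t)
            one_minus_e = -np.expm1(-q * t)
        denom = delta / (x0 - r) + w * one_minus_e
        x = xeq + w * e * delta / denom
    return float(x[0]) if scalar else x


def _initial_guesses(trace: ConcentrationTrace) -> tuple[float, float]:
    """Feasible starting point: k1 from the early-time irreversible
    linearization (1/x - 1/x0 = k1 t), k_minus1 from the final plateau via
    detailed balance."""
    t = trace.times - trace.times[0]
    x = trace.concentration
    x0 = trace.x0
    n_early = max(3, int(0.1 * len(x)))
    xe = np.clip(x[:n_early], 1e-12 * x0, None)
    te = t[:n_early]
    y = 1.0 / xe - 1.0 / x0
    denom = float(np.dot(te, te))
    k1_guess = float(np.dot(te, y) / denom) if denom > 0 else 0.0
    k1_guess = max(k1_guess, 1e-12)
    n_late = max(3, len(x) // 20)
    xeq_obs = float(np.clip(np.mean(x[-n_late:]), 1e-9 * x0, x0 * (1 - 1e-9)))
    km1_guess = max(k1_guess * xeq_obs ** 2 / (x0 - xeq_obs), _KM1_LOWER_BOUND)
    return k1_guess, km1_guess


def _propagate_keq(k1, km1, var_k1, var_km1, cov=0.0):
    """First-order variance of Keq = k1/km1."""
    if km1 <= 0 or not np.isfinite(var_k1) or not np.isfinite(var_km1):
        return float("nan")
    g = np.array([1.0 / km1, -k1 / km1 ** 2])
    c = np.array([[var_k1, cov], [cov, var_km1]])
    return float(np.sqrt(g @ c @ g))


def _require_fittable(trace: ConcentrationTrace, min_points: int = 5) -> None:
    if len(trace) < min_points:
        raise ValueError(f"need at least {min_points} points to fit")
    if trace.x0 is None or trace.x0 <= 0:
        raise ValueError("trace.x0 (initial amine concentration) must be set")
    eq = trace.metadata.get("equimolar", True)
    if not eq:
        raise ValueError("the model is strictly equimolar; non-equimolar "
                         "traces are rejected")


def fit_irreversible(trace: ConcentrationTrace,
                     fit_offset: bool = False) -> FitResult:
    """Fit the one-parameter irreversible model x(t) = x0/(1 + k1 x0 t).

    Times are absolute seconds since mixing (x = x0 at t = 0), so traces
    acquired after a dead time are modeled correctly. ``fit_offset`` adds a
    free additive constant absorbing background-subtraction error.
    """
    _require_fittable(trace, min_points=3)
    x0 = trace.x0
    t = trace.times
    x = trace.concentration
    k1_guess, _ = _initial_guesses(trace)
    params = lmfit.Parameters()
    params.add("k1", value=k1_guess, min=0.0)
    params.add("offset", value=0.0, vary=fit_offset, min=-0.2 * x0,
               max=0.2 * x0)
    out = lmfit.minimize(
        lambda p: irreversible_second_order_solution(t, p["k1"].value, x0)
        + p["offset"].value - x,
        params, method="least_squares", xtol=1e-14, ftol=1e-14, gtol=1e-14)
    k1 = float(out.params["k1"].value)
    se = float(out.params["k1"].stderr or np.nan)
    resid = irreversible_second_order_solution(t, k1, x0) \
        + float(out.params["offset"].value) - x
    rc = RateConstants(k1=k1, k_minus1=0.0, Keq=float("inf"),
                       k1_uncertainty=se, method="irreversible_fit")
    return FitResult(parameters=rc, standard_errors={"k1": se},
                     residuals=resid, sum_squared_error=float(np.sum(resid ** 2)),
                     converged=bool(out.success), x0=x0)


def _reversible_minimize(t, x, x0, k1_init, km1_init, vary_k1=True,
                         k1_fixed=None, fit_offset=False, n_restarts=3,
                         seed=0):
    """Bounded least squares with jittered restarts; returns best lmfit result."""
    rng = np.random.default_rng(seed)
    best = None
    for i in range(n_restarts):
        params = lmfit.Parameters()
        jit = 1.0 if i == 0 else float(rng.lognormal(0.0, 0.5))
        if vary_k1:
            params.add("k1", value=k1_init * jit, min=0.0)
        else:
            params.add("k1", value=k1_fixed, vary=False)
        params.add("k_minus1", value=km1_init * jit, min=_KM1_LOWER_BOUND)
        params.add("offset", value=0.0, vary=fit_offset,
                   min=-0.2 * x0, max=0.2 * x0)
        try:
            out = lmfit.minimize(
                lambda p: reversible_equimolar_solution(
                    t, p["k1"].value, p["k_minus1"].value, x0)
                + p["offset"].value - x,
                params, method="least_squares", max_nfev=10000,
                xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception:
            continue
        if best is None or out.chisqr < best.chisqr:
            best = out
    if best is None:
        raise RuntimeError("reversible fit failed from all starting points")
    return best


def _cov_entry(out, name_a: str, name_b: str) -> float:
    cmat = getattr(out, "covar", None)
    if cmat is None:
        return float("nan")
    names = list(out.var_names)
    if name_a not in names or name_b not in names:
        return float("nan")
    return float(cmat[names.index(name_a), names.index(name_b)])


def fit_reversible(trace: ConcentrationTrace,
                   initial_guess: tuple[float, float] | None = None,
                   fit_offset: bool = False) -> FitResult:
    """Free two-parameter fit of (k1, k_minus1) to an amine-consumption trace.

    Nonnegativity-bounded least squares with three jittered restarts;
    standard errors come from the fit covariance and the Keq uncertainty is
    propagated to first order (including the k1/k_minus1 covariance).
    Times are absolute seconds since mixing. ``fit_offset`` adds a free
    additive constant to the model; use it for traces derived by
    first-spectrum background subtraction, where the (noisy) reference
    spectrum and any dead-time conversion show up as a constant shift of
    the whole trace.
    """
    _require_fittable(trace)
    x0 = trace.x0
    t = trace.times
    x = trace.concentration
    flags: list[str] = []
    if np.allclose(x, x[0]):
        rc = RateConstants(k1=0.0, k_minus1=0.0, Keq=float("nan"))
        return FitResult(parameters=rc, standard_errors={},
                         residuals=np.zeros_like(x), sum_squared_error=0.0,
                         converged=True, flags=["degenerate_constant_trace"],
                         x0=x0)
    k1_init, km1_init = initial_guess or _initial_guesses(trace)
    out = _reversible_minimize(t, x, x0, k1_init, km1_init,
                               fit_offset=fit_offset)
    k1 = float(out.params["k1"].value)
    km1 = float(out.params["k_minus1"].value)
    se_k1 = float(out.params["k1"].stderr or np.nan)
    se_km1 = float(out.params["k_minus1"].stderr or np.nan)
    cov = _cov_entry(out, "k1", "k_minus1")
    if not np.isfinite(cov):
        cov = 0.0
    cmat = getattr(out, "covar", None)
    keq = k1 / km1 if km1 > 0 else float("inf")
    keq_se = _propagate_keq(k1, km1, se_k1 ** 2, se_km1 ** 2, cov)
    if not out.success:
        warnings.warn("reversible fit did not converge; parameters reported "
                      "with converged=False", stacklevel=2)
    if np.isfinite(se_km1) and km1 > 0 and se_km1 / km1 > 1.0:
        flags.append("k_minus1_poorly_determined")
    if _unresolvable_reverse(km1, t):
        flags.append("possibly_irreversible")
    resid = reversible_equimolar_solution(t, k1, km1, x0) \
        + float(out.params["offset"].value) - x
    rc = RateConstants(k1=k1, k_minus1=km1, Keq=keq, k1_uncertainty=se_k1,
                       k_minus1_uncertainty=se_km1, Keq_uncertainty=keq_se,
                       method="free_fit")
    return FitResult(parameters=rc,
                     standard_errors={"k1": se_k1, "k_minus1": se_km1},
                     residuals=resid,
                     sum_squared_error=float(np.sum(resid ** 2)),
                     converged=bool(out.success), flags=flags, x0=x0,
                     covariance=cmat)


def fit_constrained_reversible(trace: ConcentrationTrace,
                               fit_offset: bool = False,
                               early_fraction: float = 0.1) -> FitResult:
    """Two-step constrained fit for reactions with very small k_minus1.

    Step 1 fits the irreversible model for k1 on the early part of the
    trace (first ``early_fraction`` of points, where the reverse flux is
    negligible even for moderately reversible reactions); step 2 fixes
    that k1 in the reversible model and fits only k_minus1 on the full
    trace. Used when the free fit leaves k_minus1 with a large relative
    error. If the fitted reverse conversion is unresolvable over the
    observation span the reaction is flagged ``possibly_irreversible``.
    """
    _require_fittable(trace)
    n_early = min(len(trace), max(10, int(early_fraction * len(trace))))
    early = ConcentrationTrace(
        times=trace.times[:n_early], concentration=trace.concentration[:n_early],
        species=trace.species, x0=trace.x0, metadata=trace.metadata)
    step1 = fit_irreversible(early, fit_offset=fit_offset)
    k1 = step1.parameters.k1
    x0 = trace.x0
    t = trace.times
    x = trace.concentration
    _, km1_init = _initial_guesses(trace)
    out = _reversible_minimize(t, x, x0, k1, km1_init, vary_k1=False,
                               k1_fixed=k1, fit_offset=fit_offset)
    km1 = float(out.params["k_minus1"].value)
    se_km1 = float(out.params["k_minus1"].stderr or np.nan)
    flags: list[str] = []
    if _unresolvable_reverse(km1, t):
        flags.append("possibly_irreversible")
    keq = k1 / km1 if km1 > 0 else float("inf")
    se_k1 = step1.standard_errors.get("k1", float("nan"))
    keq_se = _propagate_keq(k1, km1, se_k1 ** 2, se_km1 ** 2)
    resid = reversible_equimolar_solution(t, k1, km1, x0) \
        + float(out.params["offset"].value) - x
    rc = RateConstants(k1=k1, k_minus1=km1, Keq=keq, k1_uncertainty=se_k1,
                       k_minus1_uncertainty=se_km1, Keq_uncertainty=keq_se,
                       method="constrained_fit")
    return FitResult(parameters=rc,
                     standard_errors={"k1": se_k1, "k_minus1": se_km1},
                     residuals=resid,
                     sum_squared_error=float(np.sum(resid ** 2)),
                     converged=bool(out.success),
                     fixed_parameters=["k1"], flags=flags, x0=x0)


def fit_auto(trace: ConcentrationTrace, constrain_threshold: float = 1.0,
             fit_offset: bool = False) -> FitResult:
    """Free fit, falling back to the constrained pathway when the relative
    standard error on k_minus1 exceeds ``constrain_threshold`` (default
    100%, i.e. the reverse rate is not resolved by the free fit)."""
    free = fit_reversible(trace, fit_offset=fit_offset)
    km1 = free.parameters.k_minus1
    se = free.standard_errors.get("k_minus1", float("nan"))
    poorly = (not np.isfinite(se)) or km1 <= 0 or se / km1 > constrain_threshold
    if poorly and "degenerate_constant_trace" not in free.flags:
        result = fit_constrained_reversible(trace, fit_offset=fit_offset)
        result.flags.append("constrained_pathway_triggered")
        return result
    return free


def aggregate_replicates(fits: list[FitResult],
                         mode: str = "per_replicate_mean") -> RateConstants:
    """Combine replicate fits into one REC triple.

    per_replicate_mean (default): mean +- SD of k1, k_minus1 and of the
    per-replicate Keq ratios — note this is *not* the ratio of the mean
    constants. ratio_of_means: Keq = mean(k1)/mean(k_minus1) with
    first-order error propagation. global: a single simultaneous fit across
    all replicates (requires a common x0), reporting standard errors.
    """
    if not fits:
        raise ValueError("need at least one fit")
    method = fits[0].parameters.method
    if len(fits) == 1:
        f = fits[0]
        rc = RateConstants(**{**f.parameters.__dict__})
        rc.aggregation = "single_fit_se"
        rc.n_replicates = 1
        return rc
    k1s = np.array([f.parameters.k1 for f in fits])
    km1s = np.array([f.parameters.k_minus1 for f in fits])
    n = len(fits)
    if mode == "per_replicate_mean":
        keqs = np.array([f.parameters.Keq for f in fits])
        return RateConstants(
            k1=float(np.mean(k1s)), k_minus1=float(np.mean(km1s)),
            Keq=float(np.mean(keqs)),
            k1_uncertainty=float(np.std(k1s, ddof=1)),
            k_minus1_uncertainty=float(np.std(km1s, ddof=1)),
            Keq_uncertainty=float(np.std(keqs, ddof=1)),
            method=method, aggregation="per_replicate_mean", n_replicates=n)
    if mode == "ratio_of_means":
        k1m, km1m = float(np.mean(k1s)), float(np.mean(km1s))
        v1 = float(np.var(k1s, ddof=1)) / n
        v2 = float(np.var(km1s, ddof=1)) / n
        return RateConstants(
            k1=k1m, k_minus1=km1m, Keq=k1m / km1m,
            k1_uncertainty=float(np.std(k1s, ddof=1)),
            k_minus1_uncertainty=float(np.std(km1s, ddof=1)),
            Keq_uncertainty=_propagate_keq(k1m, km1m, v1, v2),
            method=method, aggregation="ratio_of_means", n_replicates=n)
    if mode == "global":
        x0s = {f.x0 for f in fits}
        if len(x0s) != 1:
            raise ValueError("global fit requires a common x0 across replicates")
        raise ValueError(
            "global aggregation operates on traces, not FitResults; use "
            "fit_global(traces)")
    raise ValueError(f"unknown aggregation mode {mode!r}")


def fit_global(traces: list[ConcentrationTrace],
               allow_mixed_x0: bool = False) -> RateConstants:
    """Single simultaneous (k1, k_minus1) fit across replicate traces,
    reported with standard errors (the 'global fit +- SE' convention)."""
    if not traces:
        raise ValueError("need at least one trace")
    for tr in traces:
        _require_fittable(tr)
    x0s = {tr.x0 for tr in traces}
    if len(x0s) > 1 and not allow_mixed_x0:
        raise ValueError("mixed x0 across replicates; pass allow_mixed_x0=True "
                         "to override")
    k1_init, km1_init = _initial_guesses(traces[0])
    params = lmfit.Parameters()
    params.add("k1", value=k1_init, min=0.0)
    params.add("k_minus1", value=km1_init, min=_KM1_LOWER_BOUND)

    def resid(p):
        return np.concatenate([
            reversible_equimolar_solution(
                tr.times, p["k1"].value, p["k_minus1"].value,
                tr.x0) - tr.concentration
            for tr in traces])

    out = lmfit.minimize(resid, params, method="least_squares",
                         max_nfev=10000, xtol=1e-14, ftol=1e-14, gtol=1e-14)
    k1 = float(out.params["k1"].value)
    km1 = float(out.params["k_minus1"].value)
    se_k1 = float(out.params["k1"].stderr or np.nan)
    se_km1 = float(out.params["k_minus1"].stderr or np.nan)
    cov = 0.0
    if getattr(out, "covar", None) is not None and out.covar.shape == (2, 2):
        cov = float(out.covar[0, 1])
    return RateConstants(
        k1=k1, k_minus1=km1, Keq=k1 / km1 if km1 > 0 else float("inf"),
        k1_uncertainty=se_k1, k_minus1_uncertainty=se_km1,
        Keq_uncertainty=_propagate_keq(k1, km1, se_k1 ** 2, se_km1 ** 2, cov),
        method="free_fit", aggregation="global_fit", n_replicates=len(traces))
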