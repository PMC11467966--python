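# Methods

## Reversible equimolar second-order kinetics

The kinetic model assumes a single bimolecular condensation between an
amine and an aldehyde mixed at equal initial concentration x0, with no side
reactions, no pH or salt drift during acquisition, and activity
coefficients of one:

    dx/dt = -k1 x^2 + k_-1 (x0 - x),  x(0) = x0.

The rate polynomial factors over its two real roots — the equilibrium
amine concentration x_eq in (0, x0] and a negative root r — and separation
of variables gives the closed form used everywhere in the package. The
implementation is written in a cancellation-free rearrangement (the
denominator is a sum of positive terms built from expm1) so it remains
accurate through the near-irreversible regime k_-1 -> 0, where the naive
textbook expression loses all precision. The closed form is validated
against adaptive ODE integration to better than 1e-8 relative over
k1 in [1e-3, 10] L/mol/s, k_-1 in [0, 1e-3] 1/s, x0 in [1e-5, 1e-2] M.

x_eq is computed from the stable quadratic form 2 k_-1 x0 / (k_-1 +
sqrt(k_-1^2 + 4 k1 k_-1 x0)); at equilibrium the identity
K_eq = (x0 - x_eq)/x_eq^2 holds exactly and is used as an invariant test.

## Fitting

Fits are bounded nonlinear least squares (lmfit over scipy's trust-region
reflective solver), parameter tolerances 1e-14, at most 10 000 residual
evaluations, restarted from three lognormally jittered initializations
with the best sum of squares kept. Default initial guesses: k1 from the
early-time irreversible linearization 1/x - 1/x0 = k1 t on the first 10%
of points; k_-1 from the final plateau via detailed balance. Standard
errors come from the fit covariance; the K_eq uncertainty is first-order
propagation of (k1, k_-1) including their covariance.

Times are treated as absolute seconds since mixing, so a trace whose
acquisition began after a dead time (25 s in the emulated protocol) is
modeled at its true times rather than re-zeroed.

**Background-subtraction offset.** Converting UV-vis data subtracts the
first spectrum from all spectra. That reference spectrum carries its own
noise, and any imine formed during the dead time is likewise folded into
it — both appear as a *constant* shift of the whole concentration trace.
Fits on spectro-derived traces therefore include a free additive offset
(bounded at ±20% of x0). Without it, the common-mode reference noise is
aliased into the rate constants and the reported standard errors are
several-fold too small; with it, Monte-Carlo calibration at the emulated
acquisition settings shows ±3 SE coverage of 98-99%. Offset fitting is on
by default in the pipeline and off in the bare `fit_reversible`, whose
callers may have independently background-corrected data.

**Constrained pathway.** When the free fit's relative standard error on
k_-1 exceeds 100% (configurable), the reverse rate is declared unresolved
and a two-step fit runs instead: (1) the irreversible model x0/(1+k1 x0 t)
is fitted on the first 10% of the trace — restricting to early times keeps
the reverse flux out of the k1 estimate; fitting it on the full trace
instead lets k1 absorb part of the reverse signal and biases the
subsequent k_-1 by 50-90% at moderate K_eq, versus under 10% with the
early window — then (2) k1 is fixed and k_-1 fitted on the full trace. A
fitted reverse conversion k_-1 × span below 1e-3 is flagged "possibly
irreversible": such a reaction is indistinguishable from irreversible on
the experimental time scale.

**Replicate aggregation.** Three conventions are explicit, and the label
travels with every reported triple because they genuinely differ:
`per_replicate_mean` (mean ± SD of each constant *and of the per-replicate
K_eq ratios* — the default; note mean-of-ratios ≠ ratio-of-means when
replicates scatter), `ratio_of_means`, and `global` (one simultaneous fit
across replicates, ± standard error, requiring a common x0).

## Spectroscopic conversions

Detection wavelengths snap to the nearest grid point (the instrument's
0.33 nm steps) — never interpolated. Beer-Lambert calibration is ordinary
least squares of A against c·l; the intercept is estimated rather than
forced through the origin, and flagged when it exceeds 3× its standard
error. Negative concentrations produced by noise are clipped to zero with
a logged count, since the kinetic model requires x in [0, x0].

Two aldehyde-counting conventions coexist deliberately: the Schiff-test
degree of oxidation uses two aldehydes per oxidized uronic-acid unit,
while the kinetic/equilibrium aldehyde concentration of a macromer
solution counts one reactive equivalent per functionalized repeat unit,
c = m D_f / (M_Unit V) with M_Unit defaulting to 198 g/mol — the reading
under which a 2 wt% solution at 10% functionalization gives 10.1 mM.

## Binding equilibria and the cross-link fraction

A bifunctional amine arm and an aldehyde bind with association constant
K_eq; arms are assumed independent and equally reactive, intramolecular
loops and network defects are ignored (the model is an *ideal maximum*).
An aldehyde is cross-linked when its bound amine's sibling arm is also
bound, giving chi_XL = ([Im]/[Ald]0)([Im]/[Am]0). This form reproduces the
saturation drop past one equivalent of amine (bridges replaced by singly
bound pendants) and the calibration anchors chi ~ 0.82 at K_eq = 1e4 and
~ 0.15 at 1e2 for 10.1 mM aldehyde at ratio 1.

The two-amine competition solves the mass-balance cubic in free aldehyde
(coefficients from the exact competing-ligands solution; dissociation
constants K_i = 1/K_eq,i internally, association constants at every public
interface to avoid inversion bugs). Roots come from the trigonometric
closed form for the three-real-root case with a Cardano branch and a
numpy polynomial-roots fallback, followed by Newton polishing on the
monotone mass-balance function; the unique root in [0, [Ald]0] is
selected. Agreement with a bisection oracle is 1e-10 relative over 1000
random systems, and every returned state satisfies all three mass
balances to 1e-10 relative. Total amine is capped at one equivalent by
default (beyond saturation the gel softens trivially); an override flag
exists.

The softening map evaluates delta chi_XL(K1, K2) on 121-point-per-axis
log grids spanning 1e1-1e7 L/mol by default, then refines the most
negative cell by iterated local 10x regridding and reports the location
to two significant figures. With the default conditions (10.1 mM,
0.5 + 0.5 equivalents) the minimum sits at (4.5e2, 2e1) L/mol.

A note on the experimentally natural (1.3e3, 1.0e2) K_eq pair: it lies
just *outside* the model's negative region (the softening island at
K1 = 1.3e3 ends near K2 ~ 40), so the predicted titration there is a
slight stiffening (< 5%) while real gels of that chemistry soften. This is
the expected direction of the model's ideality bias — loop defects make
real networks cross-link less efficiently than the ideal maximum, shifting
the true softening region to higher K_eq — and is why the package reports
the pair as edge-of-regime rather than inside it.

## Mechanics

Affine: G' = ve R T; phantom: G' = ve (1 - 2/f) R T, f >= 3. R = 8.314
J/mol/K; temperature defaults to 293.15 K (20 C rheometry) and is explicit
everywhere. ve is reported in mol/L. Relative stiffness predictions scale
an anchored G' by chi_XL ratios (default) or by the per-amine squared
bound-fraction index sum_i (im_i/a_i0)^2, which discounts imines that
cannot bridge (partners from different amines). The index mode is meant
for endpoint comparisons of formulations; along a titration it is not
monotone, because a small dose of competitor has a high per-amine bound
fraction. Neither proportionality is claimed exact — entanglements,
loops and dangling ends are outside the model.

## Synthetic data

The generator emulates the study's acquisition: A(t) = baseline +
eps·l·(x0 - x(t)) + N(0, sigma^2) sampled every 30 s for 7200 s starting
25 s after mixing, sigma = 0.002 a.u. by default (matching the < 0.1 a.u.
signal scale of the emulated instrument). Noise is additive on
*absorbance*, not concentration, so concentration noise arises through
the epsilon division exactly as in real processing. Replicate truths are
jittered lognormally (cv 0.1 by default, preserving positivity);
titration series scale an anchor modulus by modelled chi ratios with
optional Gaussian modulus noise. Everything is deterministic given the
seed, to the byte.

What the generator does *not* emulate — hemiacetal/hydrate speciation,
salt- and pH-dependent rates, NMR lineshapes, baseline drift, loop
defects in gels — bounds what passing tests show: they certify the
analysis chain and its error calibration under the stated noise model,
not instrument-specific artifacts.

Problem sizes in the shipped studies (200 Monte-Carlo seeds for error
calibration, 121x121 softening grids, 1000 random systems for the cubic
cross-check) were chosen as the smallest sizes at which the checked
quantities are stable to well within their tolerances.

## Known limitations

- Strictly equimolar kinetics; non-equimolar traces are rejected rather
  than approximated.
- The cross-link fraction is an ideal maximum; no loop/defect or
  entanglement corrections.
- Alternative bound-fraction treatments (Bell-model, Poisson) are
  supported only through the isotherm registry interface, not
  implemented.
- Computed free-energy descriptors are consumed as a packaged table; the
  quantum-chemistry layer that produced them is out of scope.
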