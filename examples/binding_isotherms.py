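"""Equilibrium bound fraction vs Keq and vs reactive-group concentration.

The analytic single-ligand isotherm at equimolar reactive groups: the
bound fraction [Im]/[X]0 rises over ~3 decades of Keq, and changing the
concentration only slides the curve along the log-Keq axis.
"""

import numpy as np

from iminegel.equilibrium import bound_fraction_isotherm, \
    concentration_sweep_isotherm

x0 = 10.1e-3  # mol/L, the study's reactive-group concentration
keqs = np.array([1e1, 1e2, 1e3, 1e4, 1e5])
curve = bound_fraction_isotherm(x0, keqs)
print("Keq (L/mol)   bound fraction at [X]0 = 10.1 mM")
for k, f in zip(keqs, curve.values):
    print(f"  {k:8.0e}      {f:.3f}")

sweep = concentration_sweep_isotherm(1e3, np.array([1e-4, 1e-3, 1e-2, 1e-1]))
print("\n[X]0 (M)      bound fraction at Keq = 1e3")
for c, f in zip(sweep.axis1, sweep.values):
    print(f"  {c:8.0e}      {f:.3f}")
print("\nHalving the concentration is equivalent to halving Keq: pick the")
print("concentration regime to match the chemistry's Keq, or vice versa.")
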