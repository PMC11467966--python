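"""Rubber-elasticity links between shear modulus and chain concentration.

Affine networks: G' = ve * R * T, with ve the molar concentration of
elastically active chain segments. Phantom networks allow junction
fluctuation and carry the (1 - 2/f) correction for junction
functionality f: G' = ve * (1 - 2/f) * R * T. For highly functional
side-chain-decorated macromers f is large and phantom converges to
affine.

Relative stiffness predictions assume G' proportional to the total
cross-linked fraction chi_XL, so a titration series of formulations can
be anchored to a single measured modulus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .equilibrium import (
    CompetitiveSystem,
    competitive_equilibrium,
    per_amine_crosslink_index,
    total_crosslinked_fraction,
)

__all__ = [
    "R_GAS",
    "DEFAULT_T",
    "MACROMER_DERIVED_VE_M",
    "NetworkModel",
    "MechanicalPrediction",
    "ve_from_modulus",
    "modulus_from_ve",
    "relative_softening_prediction",
]

R_GAS = 8.314  # J/mol/K
DEFAULT_T = 293.15  # K (20 C, the rheometry temperature)

# Reference value for a 2 wt% oxidized-alginate gel computed from macromer
# molecular weight/concentration/functionality (synthetic-network counting,
# shipped as a constant; it is not recomputed here).
MACROMER_DERIVED_VE_M = 4.3e-3


@dataclass
class NetworkModel:
    kind: str = "affine"  # "affine" | "phantom"
    functionality: float | None = None  # arms per junction, phantom only
    temperature: float = DEFAULT_T  # K

    def __post_init__(self) -> None:
        if self.kind not in ("affine", "phantom"):
            raise ValueError("kind must be 'affine' or 'phantom'")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.kind == "phantom":
            if self.functionality is None or self.functionality < 3:
                raise ValueError("phantom model requires functionality f >= 3")

    @property
    def prefactor(self) -> float:
        """Dimensionless factor multiplying ve*R*T in G'."""
        if self.kind == "affine":
            return 1.0
        return 1.0 - 2.0 / self.functionality


@dataclass
class MechanicalPrediction:
    ve: float  # mol/L
    G_prime: float  # Pa
    model: NetworkModel

    def __post_init__(self) -> None:
        if self.ve < 0 or self.G_prime < 0:
            raise ValueError("ve and G' must be nonnegative")


def ve_from_modulus(G_prime: float, model: NetworkModel) -> MechanicalPrediction:
    """Elastically active chain concentration (mol/L) from shear storage
    modulus: ve = G' / (prefactor * R * T). G' in Pa gives ve in mol/m^3,
    converted to mol/L."""
    if G_prime < 0:
        raise ValueError("G' must be nonnegative")
    ve_m3 = G_prime / (model.prefactor * R_GAS * model.temperature)
    return MechanicalPrediction(ve=ve_m3 / 1000.0, G_prime=G_prime, model=model)


def modulus_from_ve(ve: float, model: NetworkModel) -> MechanicalPrediction:
    """Exact algebraic inverse of :func:`ve_from_modulus`."""
    if ve < 0:
        raise ValueError("ve must be nonnegative")
    G = ve * 1000.0 * model.prefactor * R_GAS * model.temperature
    return MechanicalPrediction(ve=ve, G_prime=G, model=model)


def relative_softening_prediction(series: list[CompetitiveSystem],
                                  anchor_G: float,
                                  mode: str = "chi_total") -> np.ndarray:
    """Predicted G' series for a list of formulations, anchored to the
    measured modulus of the first.

    G'_i = anchor_G * index_i / index_0 where the index is either the total
    cross-linked fraction (default, G' proportional to cross-link
    concentration) or the per-amine squared-bound-fraction index
    (``mode="per_amine_index"``), which discounts non-bridging imines in
    mixed systems.
    """
    if not series:
        raise ValueError("series must be nonempty")
    if anchor_G <= 0:
        raise ValueError("anchor_G must be positive")
    if mode not in ("chi_total", "per_amine_index"):
        raise ValueError("mode must be 'chi_total' or 'per_amine_index'")
    indices = []
    for system in series:
        state = competitive_equilibrium(system)
        if mode == "chi_total":
            indices.append(total_crosslinked_fraction(state, system))
        else:
            indices.append(per_amine_crosslink_index(
                (state.im1, state.im2), (system.a1_0, system.a2_0)))
    indices = np.asarray(indices)
    if indices[0] <= 0:
        raise ValueError("the anchor formulation has zero cross-link fraction")
    return anchor_G * indices / indices[0]
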