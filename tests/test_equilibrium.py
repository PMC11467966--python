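"""Single and competitive binding equilibria, softening map, isotherms."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from iminegel.equilibrium import (
    BindingSystem,
    CompetitiveSystem,
    bound_fraction_isotherm,
    competitive_equilibrium,
    concentration_sweep_isotherm,
    correlate_descriptor_vs_log_rec,
    crosslinked_fraction,
    fraction_vs_ratio_curve,
    load_dft_descriptors,
    load_rec_table,
    load_rec_uvvis_vs_nmr,
    per_amine_crosslink_index,
    register_isotherm_model,
    single_ligand_equilibrium,
    softening_map,
    total_crosslinked_fraction,
    _mass_balance,
)

ALD0 = 10.1e-3  # mol/L, the 2 wt% oxidized-alginate aldehyde concentration


def bisection_oracle(system: CompetitiveSystem) -> float:
    """Independent root-finder on the monotone mass-balance equation."""
    return brentq(lambda x: _mass_balance(x, system), 0.0, system.ald0,
                  xtol=1e-18, rtol=1e-15)


def random_system(rng) -> CompetitiveSystem:
    ald0 = 10 ** rng.uniform(-4, -1)
    chi1 = rng.uniform(0.05, 0.9)
    chi2 = rng.uniform(0.0, 1.0 - chi1)
    return CompetitiveSystem.from_keq(
        ald0, chi1 * ald0, chi2 * ald0,
        10 ** rng.uniform(0, 7), 10 ** rng.uniform(0, 7))


class TestSingleLigand:
    def test_zero_keq(self):
        assert single_ligand_equilibrium(ALD0, ALD0, 0.0) == 0.0

    def test_equimolar_strong_binding(self):
        im = single_ligand_equilibrium(ALD0, ALD0, 1e4)
        assert im == pytest.approx(9.144e-3, rel=1e-3)
        assert im / ALD0 == pytest.approx(0.9053, rel=1e-3)

    def test_half_equivalent_oxime(self):
        im = single_ligand_equilibrium(ALD0, ALD0 / 2, 1.3e3)
        assert im == pytest.approx(4.445e-3, rel=1e-3)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(ald0=st.floats(1e-4, 1e-1), ratio=st.floats(0.01, 2.0),
           logk=st.floats(0.0, 7.0))
    def test_keq_residual_identity(self, ald0, ratio, logk):
        am0, keq = ratio * ald0, 10 ** logk
        im = single_ligand_equilibrium(ald0, am0, keq)
        assert 0.0 <= im <= min(ald0, am0)
        assert im / ((ald0 - im) * (am0 - im)) == pytest.approx(keq, rel=1e-8)


class TestCrosslinkedFraction:
    def test_printed_anchors(self):
        chi_hi = crosslinked_fraction(BindingSystem(ALD0, 1.0, 1e4))
        chi_lo = crosslinked_fraction(BindingSystem(ALD0, 1.0, 1e2))
        assert chi_hi == pytest.approx(0.8, abs=0.03)
        assert chi_lo == pytest.approx(0.15, abs=0.03)

    def test_no_amine_gives_zero(self):
        assert crosslinked_fraction(BindingSystem(ALD0, 0.0, 1e4)) == 0.0

    def test_saturation_limit(self):
        chi = crosslinked_fraction(BindingSystem(ALD0, 1.0, 1e12))
        assert chi == pytest.approx(1.0, abs=1e-3)

    def test_monotone_in_keq_below_saturation(self):
        keqs = np.logspace(1, 7, 40)
        for chi_am in (0.3, 0.7, 1.0):
            vals = [crosslinked_fraction(BindingSystem(ALD0, chi_am, k))
                    for k in keqs]
            assert np.all(np.diff(vals) >= -1e-12)


class TestFractionCurve:
    def test_zero_keq_flat(self):
        curve = fraction_vs_ratio_curve(0.0, ALD0)
        assert np.all(curve.values == 0.0)

    def test_strong_binder_drops_past_saturation(self):
        curve = fraction_vs_ratio_curve(1e7, ALD0)
        chi = dict(zip(np.round(curve.axis1, 3), curve.values))
        assert chi[1.4] < chi[1.0]

    def test_drop_magnitude_shrinks_with_keq(self):
        def drop(keq):
            c = fraction_vs_ratio_curve(keq, ALD0)
            return float(np.max(c.values) - c.values[-1])
        assert drop(1e7) > drop(1e1)


class TestCompetitive:
    def test_degenerates_to_single_ligand(self):
        s = CompetitiveSystem.from_keq(ALD0, 5.05e-3, 0.0, 1.3e3, 1e2)
        st_ = competitive_equilibrium(s)
        assert st_.im1 == pytest.approx(
            single_ligand_equilibrium(ALD0, 5.05e-3, 1.3e3), rel=1e-10)
        assert st_.im2 == 0.0

    def test_symmetric_system_splits_evenly(self):
        s = CompetitiveSystem.from_keq(ALD0, ALD0 / 2, ALD0 / 2, 1e3, 1e3)
        st_ = competitive_equilibrium(s)
        assert st_.im1 == pytest.approx(st_.im2, rel=1e-12)
        assert st_.im1 == pytest.approx(3.691e-3, rel=1e-3)
        assert st_.im1 + st_.im2 == pytest.approx(
            single_ligand_equilibrium(ALD0, ALD0, 1e3), rel=1e-10)

    def test_label_swap_symmetry(self, rng):
        for _ in range(20):
            s = random_system(rng)
            a = competitive_equilibrium(s)
            b = competitive_equilibrium(CompetitiveSystem(
                ald0=s.ald0, a1_0=s.a2_0, a2_0=s.a1_0, K_A1=s.K_A2,
                K_A2=s.K_A1))
            assert a.im1 == pytest.approx(b.im2, rel=1e-12, abs=1e-300)
            assert a.im2 == pytest.approx(b.im1, rel=1e-12, abs=1e-300)

    def test_matches_bisection_oracle(self, rng):
        for _ in range(300):
            s = random_system(rng)
            st_ = competitive_equilibrium(s)
            oracle = bisection_oracle(s)
            assert st_.ald_free == pytest.approx(oracle, rel=1e-10,
                                                 abs=1e-16 * s.ald0)

    def test_mass_balance(self, rng):
        for _ in range(100):
            s = random_system(rng)
            st_ = competitive_equilibrium(s)
            st_.check_mass_balance(s)  # raises on violation

    def test_excess_amine_rejected_without_override(self):
        with pytest.raises(ValueError, match="saturation"):
            CompetitiveSystem.from_keq(ALD0, ALD0, ALD0, 1e3, 1e3)
        s = CompetitiveSystem.from_keq(ALD0, ALD0, ALD0, 1e3, 1e3,
                                       allow_excess=True)
        competitive_equilibrium(s).check_mass_balance(s)


class TestTotalFraction:
    def test_single_amine_equivalence(self):
        s = CompetitiveSystem.from_keq(ALD0, 5.05e-3, 0.0, 1.3e3, 1e2)
        total = total_crosslinked_fraction(competitive_equilibrium(s), s)
        single = crosslinked_fraction(BindingSystem(ALD0, 0.5, 1.3e3))
        assert total == pytest.approx(single, rel=1e-10)

    def test_strong_binders_saturate(self):
        s = CompetitiveSystem.from_keq(ALD0, ALD0 / 2, ALD0 / 2, 1e12, 1e12)
        total = total_crosslinked_fraction(competitive_equilibrium(s), s)
        assert total == pytest.approx(1.0, abs=1e-3)

    def test_weak_competitor_softens(self):
        # the validated emergent behavior: adding a weak competitor to a
        # moderate-Keq gel removes cross-links
        base = crosslinked_fraction(BindingSystem(ALD0, 0.5, 4.5e2))
        s = CompetitiveSystem.from_keq(ALD0, ALD0 / 2, ALD0 / 2, 4.5e2, 2e1)
        mixed = total_crosslinked_fraction(competitive_equilibrium(s), s)
        assert mixed < base

    def test_identical_competitor_stiffens(self):
        for keq in (1e2, 1e3, 1e5):
            base = crosslinked_fraction(BindingSystem(ALD0, 0.5, keq))
            s = CompetitiveSystem.from_keq(ALD0, ALD0 / 2, ALD0 / 2, keq, keq)
            mixed = total_crosslinked_fraction(competitive_equilibrium(s), s)
            assert mixed > base


class TestSofteningMap:
    def test_coarse_map_properties(self):
        grid = np.logspace(1, 7, 25)
        surface, report = softening_map(grid, grid, refine=False)
        assert report["n_negative_cells"] > 0
        # inert competitor column (lowest Keq): |delta| small
        assert np.all(np.abs(surface.values[:, 0]) <
                      np.abs(surface.values).max())
        # diagonal (identical cross-linker) is nonnegative
        diag = np.diag(surface.values)
        assert np.all(diag >= -1e-12)

    def test_argmin_location(self):
        surface, report = softening_map()
        assert report["Keq_A1_max_softening"] == pytest.approx(4.5e2, rel=0.5)
        assert report["Keq_A2_max_softening"] == pytest.approx(2e1, rel=0.5)
        assert report["delta_chi_min"] < 0

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            softening_map(np.array([]), np.array([1.0]))


class TestPerAmineIndex:
    def test_examples(self):
        assert per_amine_crosslink_index([1e-3], [1e-3]) == pytest.approx(1.0)
        assert per_amine_crosslink_index([0.0, 0.0], [1e-3, 1e-3]) == 0.0
        hi = per_amine_crosslink_index([0.8e-3, 0.0], [1e-3, 1e-3])
        lo = per_amine_crosslink_index([0.6e-3, 0.5e-3], [1e-3, 1e-3])
        assert hi == pytest.approx(0.64)
        assert lo == pytest.approx(0.61)
        # softening despite higher total imine: 4.7% decrease
        assert (hi - lo) / hi == pytest.approx(0.047, abs=0.001)

    def test_errors(self):
        with pytest.raises(ValueError):
            per_amine_crosslink_index([1e-3], [0.0])
        with pytest.raises(ValueError):
            per_amine_crosslink_index([2e-3], [1e-3])


class TestIsotherms:
    def test_weak_binding_vanishes(self):
        curve = bound_fraction_isotherm(ALD0, np.array([1e-3]))
        assert curve.values[0] < 1e-4

    def test_study_concentration_anchor(self):
        curve = bound_fraction_isotherm(ALD0, np.array([1e4]))
        assert curve.values[0] == pytest.approx(0.905, abs=0.002)

    def test_shape_invariance_in_log_keq(self):
        # doubling x0 halves the Keq needed for any given bound fraction
        keqs = np.logspace(0, 7, 200)
        a = bound_fraction_isotherm(ALD0, keqs).values
        b = bound_fraction_isotherm(2 * ALD0, keqs / 2).values
        np.testing.assert_allclose(a, b, rtol=1e-9)

    def test_monotone_in_keq_and_x0(self):
        keqs = np.logspace(0, 7, 50)
        assert np.all(np.diff(bound_fraction_isotherm(ALD0, keqs).values) > 0)
        sweep = concentration_sweep_isotherm(1e3)
        assert np.all(np.diff(sweep.values) > 0)

    def test_unknown_model_rejected_listing_registered(self):
        with pytest.raises(ValueError, match="analytic"):
            bound_fraction_isotherm(ALD0, model="bell")

    def test_pluggable_model(self):
        register_isotherm_model("constant_half", lambda x0, k: np.full(k.size, 0.5))
        try:
            c = bound_fraction_isotherm(ALD0, np.array([1.0, 10.0]),
                                        model="constant_half")
            assert np.all(c.values == 0.5)
        finally:
            from iminegel.equilibrium import _ISOTHERM_MODELS
            _ISOTHERM_MODELS.pop("constant_half")


class TestDescriptorCorrelation:
    def test_collinear_r2_is_one(self):
        x = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        y = 2 * x + 1
        res = correlate_descriptor_vs_log_rec(x, y)
        assert res["r2"] == pytest.approx(1.0)

    def test_intermediate_breakdown_energy_tracks_forward_rate(self):
        # for the oxidized-alginate series the breakdown free energy of the
        # tetrahedral intermediate correlates strongly with log k1
        desc = load_dft_descriptors()
        rec = load_rec_table()
        sub = rec[(rec.aldehyde == 2) & rec.k1_L_mol_s.notna()].set_index("amine")
        res = correlate_descriptor_vs_log_rec(
            desc["dG2_over_RT"], np.log10(sub["k1_L_mol_s"]))
        assert res["n"] == 5
        assert res["r2"] == pytest.approx(0.9, abs=0.05)

    def test_shuffled_pairs_destroy_correlation(self, rng):
        desc = load_dft_descriptors()
        rec = load_rec_table()
        sub = rec[(rec.aldehyde == 2) & rec.k1_L_mol_s.notna()].set_index("amine")
        y = np.log10(sub["k1_L_mol_s"])
        r2s = []
        for _ in range(50):
            perm = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
            r2s.append(correlate_descriptor_vs_log_rec(
                desc["dG2_over_RT"], perm)["r2"])
        assert np.median(r2s) < 0.5

    def test_mismatched_identities_rejected(self):
        x = pd.Series([1.0, 2.0], index=["a", "b"])
        y = pd.Series([1.0, 2.0], index=["c", "d"])
        with pytest.raises(ValueError, match="paired"):
            correlate_descriptor_vs_log_rec(x, y)


class TestFixtures:
    def test_rec_table_keq_consistency(self):
        # printed Keq columns must agree with k1/k_minus1 within the
        # printed uncertainties (mean-of-ratios rows can differ)
        rec = load_rec_table()
        row = rec[(rec.aldehyde == 3) & (rec.amine == 7)].iloc[0]
        assert row.k1_L_mol_s / row.k_minus1_s == pytest.approx(
            row.Keq_L_mol, abs=row.Keq_sd)
        row = rec[(rec.aldehyde == 1) & (rec.amine == 5)].iloc[0]
        assert row.k1_L_mol_s / row.k_minus1_s == pytest.approx(
            row.Keq_L_mol, abs=row.Keq_sd)

    def test_method_comparison_table_loads(self):
        t2 = load_rec_uvvis_vs_nmr()
        assert set(t2.method) == {"uvvis", "nmr"}
        uv = t2[(t2.method == "uvvis") & (t2.amine == 5)].iloc[0]
        assert uv.k1_L_mol_s == pytest.approx(0.058)

    def test_descriptor_table_dimensionless_conversion(self):
        d = load_dft_descriptors()
        # RT at 298.15 K is ~0.5925 kcal/mol
        assert d.loc[5, "drG_over_RT"] == pytest.approx(-7.77 / 0.5925,
                                                        rel=1e-3)
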