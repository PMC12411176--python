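"""Biomass pseudo-reactions, the M-matrix growth law, unit steady states
and the reduced two-unit allocation model."""

import numpy as np
import pytest

from selfcell import (
    BiomassComposition,
    biomass_pseudoreaction,
    build_m_matrix,
    fixture_unit_network,
    reduced_allocation_scan,
    scenario_sweep,
    unit_steady_state,
)
from selfcell.macro_units import molar_coefficients, optimal_allocation
from selfcell.network_core import rank_and_nullspace

WEIGHTS = {"A": 150.0, "B": 100.0, "C": 100.0, "D": 200.0}
FRACTIONS = {"A": 0.35, "B": 0.15, "C": 0.30, "D": 0.20}


class TestBiomassPseudoreaction:
    def test_printed_molar_coefficients(self):
        molar = molar_coefficients(FRACTIONS, WEIGHTS)
        assert molar["A"] == pytest.approx(2.333e-3, abs=5e-7)
        assert molar["B"] == pytest.approx(1.5e-3)
        assert molar["C"] == pytest.approx(3e-3)
        assert molar["D"] == pytest.approx(1e-3)

    def test_drain_reaction_shape(self):
        rxn = biomass_pseudoreaction(FRACTIONS, WEIGHTS)
        assert all(coef < 0 for coef in rxn.stoich.values())  # no products
        assert not rxn.is_internal
        assert rxn.allows_mass_loss

    def test_mass_closure_is_exactly_one_gram(self):
        rxn = biomass_pseudoreaction(FRACTIONS, WEIGHTS)
        drained = -sum(
            coef * WEIGHTS[cid] for cid, coef in rxn.stoich.items()
        )
        assert drained == pytest.approx(1000.0)  # mg/gDW per unit mu

    @pytest.mark.parametrize(
        "fractions",
        [
            {"A": 0.5, "B": 0.5},
            {"A": 0.1, "B": 0.2, "C": 0.3, "D": 0.4},
        ],
    )
    def test_closure_for_any_valid_composition(self, fractions):
        rxn = biomass_pseudoreaction(fractions, WEIGHTS)
        drained = -sum(
            coef * WEIGHTS[cid] for cid, coef in rxn.stoich.items()
        )
        assert drained == pytest.approx(1000.0)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            BiomassComposition({"A": 0.5, "B": 0.4})

    def test_missing_weight_is_an_error(self):
        with pytest.raises(KeyError, match="Z"):
            biomass_pseudoreaction({"Z": 1.0}, WEIGHTS)


class TestMMatrix:
    def test_zero_concentrations_recover_identity(self):
        w = np.array(list(WEIGHTS.values()))
        m = build_m_matrix(np.zeros(4), w)
        np.testing.assert_array_equal(m.matrix, np.eye(4))

    def test_algebraic_identity_mnr_equals_nr_minus_mu_c(self, toy_net):
        rng = np.random.default_rng(2)
        w = toy_net.weights()
        N = toy_net.N
        for _ in range(10):
            c = rng.uniform(0, 0.5, size=4)
            r = rng.normal(size=7)
            m = build_m_matrix(c, w)
            mu = (w @ N @ r) / 1000.0
            np.testing.assert_allclose(
                m.matrix @ N @ r, N @ r - mu * c, atol=1e-12
            )

    def test_full_mass_accounting_annihilates_weights(self, toy_net):
        w = toy_net.weights()
        c = 1000.0 * w / np.sum(w**2)  # w^T c / 1000 = 1
        m = build_m_matrix(c, w)
        assert np.max(np.abs(w @ m.matrix)) < 1e-9
        # hence w^T M N r = 0 for every flux vector
        rng = np.random.default_rng(0)
        r = rng.normal(size=7)
        assert abs(w @ m.matrix @ toy_net.N @ r) < 1e-9

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            build_m_matrix(np.zeros(3), np.ones(4))


class TestUnitSteadyState:
    def test_no_growth_no_synthesis(self):
        _, model = fixture_unit_network("two-unit")
        table = unit_steady_state(model, 0.0)
        assert (table["mass_rate"] == 0).all()

    def test_rates_scale_with_mass_fractions(self):
        _, model = fixture_unit_network("two-unit", fB1=0.4)
        mu = 0.7
        table = unit_steady_state(model, mu, monomer_weights={"A": 100.0})
        # r3 = r2 * B2/B1 and both ratios recover mu
        assert table.loc["B2", "mass_rate"] == pytest.approx(
            table.loc["B1", "mass_rate"] * 0.6 / 0.4
        )
        for uid in ("B1", "B2"):
            assert table.loc[uid, "mass_rate"] / table.loc[
                uid, "mass_fraction"
            ] == pytest.approx(mu)

    def test_molar_rate_uses_unit_weight(self):
        _, model = fixture_unit_network("two-unit", gamma2=500.0)
        table = unit_steady_state(model, 1.0, monomer_weights={"A": 100.0})
        # unit weight gamma2 * wA = 5e4 g/mol
        assert table.loc["B1", "molar_rate"] == pytest.approx(
            1000.0 * table.loc["B1", "mass_rate"] / 5e4
        )


class TestTwoUnitKernels:
    def test_growth_mode_of_mass_fraction_form(self):
        # with f_A = 0 the growth-mode kernel vector of M N has entries
        # (1/wA, 0, 1, 1): both synthesis rates equal one
        fB1, wA = 0.5, 100.0
        net, _ = fixture_unit_network("two-unit-massfrac", fB1=fB1, wA=wA)
        w = net.weights()
        c = np.array([0.0, 1000.0 * fB1 / w[1], 1000.0 * (1 - fB1) / w[2]])
        mn = build_m_matrix(c, w).matrix @ net.N
        basis = rank_and_nullspace(mn)
        assert basis.dimension == 2
        # solve for the combination with r2 = 1, r1 = 0
        coef = np.linalg.lstsq(basis.K[[1, 2], :], [0.0, 1.0], rcond=None)[0]
        growth = basis.K @ coef
        np.testing.assert_allclose(
            growth, [1.0 / wA, 0.0, 1.0, 1.0], atol=1e-9
        )

    def test_overflow_mode_bypasses_biomass(self):
        net, _ = fixture_unit_network("two-unit-massfrac")
        w = net.weights()
        c = np.array([0.0, 1000.0 * 0.5 / w[1], 1000.0 * 0.5 / w[2]])
        mn = build_m_matrix(c, w).matrix @ net.N
        basis = rank_and_nullspace(mn)
        coef = np.linalg.lstsq(basis.K[[1, 2], :], [1.0, 0.0], rcond=None)[0]
        overflow = basis.K @ coef
        np.testing.assert_allclose(overflow, [1.0, 1.0, 0.0, 0.0], atol=1e-9)

    def test_monomer_form_growth_mode_ratio(self):
        # the unit-synthesis rates relate as r3/r2 = (B2/B1) * (W1/W2);
        # with equal unit weights this is B2/B1
        net, model = fixture_unit_network("two-unit", fB1=0.25)
        w = net.weights()
        c = np.array([0.0, 1000.0 * 0.25 / w[1], 1000.0 * 0.75 / w[2]])
        mn = build_m_matrix(c, w).matrix @ net.N
        basis = rank_and_nullspace(mn)
        coef = np.linalg.lstsq(
            basis.K[[1, 2], :], [0.0, 1.0], rcond=None
        )[0]
        growth = basis.K @ coef
        assert growth[3] / growth[2] == pytest.approx(0.75 / 0.25)


class TestAllocationScan:
    def test_boundary_points_have_zero_growth(self):
        table, _ = reduced_allocation_scan(None, 3.0, 1.5, grid=11)
        first, last = table.iloc[0], table.iloc[-1]
        assert first["B1"] == 0.0 and first["r0"] == 0.0
        assert last["B2"] == 0.0 and last["mu"] == 0.0

    def test_optimum_matches_continuous_oracle(self):
        k1, k2 = 3.0, 1.5
        table, optimum = reduced_allocation_scan(None, k1, k2, grid=401)
        oracle = optimal_allocation(k1, k2)
        assert optimum["B1"] == pytest.approx(
            oracle["B1"], abs=1.0 / 400
        )
        # one grid step off the kink costs at most k2 * step in mu
        assert optimum["mu"] == pytest.approx(oracle["mu"], abs=k2 / 400)
        # closed form: B1* = k2/(k1+k2), mu* = k1 k2/(k1+k2)
        assert oracle["B1"] == pytest.approx(k2 / (k1 + k2), abs=1e-6)
        assert oracle["mu"] == pytest.approx(k1 * k2 / (k1 + k2), abs=1e-6)

    def test_infeasible_branch_is_flagged(self):
        table, optimum = reduced_allocation_scan(None, 3.0, 1.5, grid=101)
        left = table[table["B1"] < optimum["B1"] - 0.02]
        assert (~left["feasible"]).all()  # overflow would have to reverse
        assert (left["r1"] < 0).all()

    def test_steady_state_holds_on_every_grid_point(self):
        table, _ = reduced_allocation_scan(None, 2.0, 5.0, grid=51)
        np.testing.assert_allclose(
            table["r0"] - table["r1"] - table["r2"], 0.0, atol=1e-12
        )

    def test_grid_too_small_rejected(self):
        with pytest.raises(ValueError):
            reduced_allocation_scan(None, 1.0, 1.0, grid=2)


class TestScenarioSweep:
    def test_growth_monotone_and_saturating_in_substrate(self):
        values = [0.05, 0.1, 0.2, 0.5, 1.0, 2.0, 5.0, 20.0]
        table = scenario_sweep(None, "substrate_limitation", values)
        mu = table["mu"].to_numpy()
        assert all(b >= a - 1e-12 for a, b in zip(mu, mu[1:]))
        # hyperbolic, not linear: the gain per doubling shrinks
        gain_low = mu[1] - mu[0]
        gain_high = mu[-1] - mu[-2]
        assert gain_high < gain_low
        assert mu[-1] < 1.5 * mu[4]  # approaches the k2 B plateau

    def test_uptake_sector_grows_under_limitation(self):
        table = scenario_sweep(
            None, "substrate_limitation", [0.2, 1.0, 5.0]
        )
        b1 = table["B1"].to_numpy()
        assert b1[0] > b1[1] > b1[2]  # scarcity shifts mass to uptake

    def test_burden_reduces_growth_monotonically(self):
        table = scenario_sweep(
            None, "heterologous_burden", [0.0, 0.2, 0.5, 0.8, 1.0]
        )
        mu = table["mu"].to_numpy()
        assert all(b <= a + 1e-12 for a, b in zip(mu, mu[1:]))
        assert mu[-1] == 0.0

    def test_unknown_scenario(self):
        with pytest.raises(ValueError, match="scenario"):
            scenario_sweep(None, "phage_attack", [1.0])
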