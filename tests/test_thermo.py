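"""Gibbs-energy bookkeeping, loop laws, loopless FBA, MDF."""

import math

import numpy as np
import pytest

from selfcell import (
    Compound,
    Network,
    Objective,
    Reaction,
    ThermoSpec,
    check_cycle_consistency,
    dg0_from_keq,
    internal_cycle_basis,
    keq_from_dg0,
    loopless_fba,
    mdf,
    scaled_delta_g,
    sign_loop_test,
    sign_pattern,
    solve_fba,
    tfba_with_concentrations,
)
from selfcell.thermo import DEFAULT_RT, LooplessConfig, keq_dg0_interconvert


class TestKeqDg0:
    def test_equilibrium_constant_one_means_zero_energy(self):
        assert dg0_from_keq(1.0) == 0.0

    @pytest.mark.parametrize("keq", [1.5, 10.0, 1e6])
    def test_favourable_reactions_have_negative_dg0(self, keq):
        assert dg0_from_keq(keq) < 0
        assert dg0_from_keq(1.0 / keq) > 0

    @pytest.mark.parametrize("keq", [1e-8, 0.3, 1.0, 42.0, 1e9])
    def test_round_trip(self, keq):
        assert keq_from_dg0(dg0_from_keq(keq)) == pytest.approx(
            keq, rel=1e-12
        )
        assert keq_dg0_interconvert(
            keq_dg0_interconvert(keq), direction="dg0_to_keq"
        ) == pytest.approx(keq, rel=1e-12)

    def test_nonpositive_keq_rejected(self):
        with pytest.raises(ValueError):
            dg0_from_keq(0.0)

    def test_decade_of_keq_shifts_dg_by_rt_ln10(self):
        # R = 8.315 J/mol/K, T = 300 K: RT ln 10 = 5.74 kJ/mol
        shift = dg0_from_keq(3.0) - dg0_from_keq(30.0)
        assert shift == pytest.approx(DEFAULT_RT * math.log(10.0))
        assert shift == pytest.approx(5.744, abs=1e-3)


class TestScaledDeltaG:
    def test_zero_x_and_zero_dg0(self, toy_net):
        spec = ThermoSpec(dg0_prime={r: 0.0 for r in ["r1", "r2", "r3", "r4"]})
        dg, dg_scaled = scaled_delta_g(spec, toy_net, np.zeros(4))
        np.testing.assert_allclose(dg, 0.0)
        np.testing.assert_allclose(dg_scaled, 0.0)

    def test_vanishes_at_equilibrium_concentrations(self, toy_net):
        # parameterize dG0' from K_eq; at x with mass-action ratio K_eq the
        # reaction energy is exactly zero (checked for r3: C -> B)
        keq = 7.5
        spec = ThermoSpec(
            dg0_prime={
                "r1": 0.0,
                "r2": 0.0,
                "r3": dg0_from_keq(keq),
                "r4": 0.0,
            }
        )
        x = np.zeros(4)
        x[toy_net.compound_index("B")] = math.log(keq * 0.02)
        x[toy_net.compound_index("C")] = math.log(0.02)
        dg, _ = scaled_delta_g(spec, toy_net, x)
        assert dg[2] == pytest.approx(0.0, abs=1e-12)

    def test_missing_dg0_names_reaction(self, toy_net):
        spec = ThermoSpec(dg0_prime={"r1": 0.0})
        with pytest.raises(KeyError, match="r2"):
            scaled_delta_g(spec, toy_net, np.zeros(4))


class TestCycleConsistency:
    def test_printed_cycle_identity(self, toy_net):
        # -dG2 - 2 dG3 + dG4 = 0 <=> K_eq2 K_eq3^2 = K_eq4
        spec = ThermoSpec(
            dg0_prime={
                "r1": -3.0,
                "r2": dg0_from_keq(2.0),
                "r3": dg0_from_keq(3.0),
                "r4": dg0_from_keq(18.0),
            }
        )
        report = check_cycle_consistency(
            spec, internal_cycle_basis(toy_net), toy_net
        )
        assert report.consistent

    def test_wrong_keq_is_flagged(self, toy_net):
        spec = ThermoSpec(
            dg0_prime={
                "r1": 0.0,
                "r2": dg0_from_keq(2.0),
                "r3": dg0_from_keq(3.0),
                "r4": dg0_from_keq(17.0),  # should be 18
            }
        )
        report = check_cycle_consistency(
            spec, internal_cycle_basis(toy_net), toy_net
        )
        assert not report.consistent

    def test_cycle_free_network_is_trivially_consistent(self, chain_net):
        spec = ThermoSpec(dg0_prime={"x2y": -123.4})
        report = check_cycle_consistency(
            spec, internal_cycle_basis(chain_net), chain_net
        )
        assert report.consistent
        assert report.residuals.size == 0 or np.allclose(report.residuals, 0)


class TestSignLoopTest:
    def test_printed_values(self):
        s_c = [0, -1, -1, 1]  # signs of the (0, -1, -2, 1) cycle
        lhs, rhs, passes = sign_loop_test(s_c, [0, 1, 1, 1])
        assert (lhs, rhs, passes) == (1, 3, True)

    def test_flux_running_in_cycle_fails(self):
        s_c = [0, -1, -1, 1]
        lhs, rhs, passes = sign_loop_test(s_c, s_c)
        assert lhs == rhs == 3
        assert not passes

    def test_sign_flip_is_irrelevant(self):
        s_c = [0, -1, -1, 1]
        flipped = [0, 1, 1, -1]
        assert sign_loop_test(s_c, flipped)[:2] == (3, 3)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            sign_loop_test([1, -1], [1])

    def test_non_sign_entries_rejected(self):
        with pytest.raises(ValueError):
            sign_loop_test([2, 0], [1, 0])


class TestLooplessFba:
    def test_objective_no_longer_pinned_at_flux_bound(self, toy_net):
        plain = solve_fba(toy_net, Objective.maximize("r3"), fixed={"r0": 1.0})
        loopless = loopless_fba(
            toy_net, Objective.maximize("r3"), fixed={"r0": 1.0}
        )
        assert loopless.ok
        assert loopless.objective_value < plain.objective_value
        assert loopless.objective_value == pytest.approx(1.0, abs=1e-5)

    def test_no_net_cycle_flux(self, toy_net):
        sol = loopless_fba(toy_net, Objective.maximize("r3"), fixed={"r0": 1.0})
        basis = internal_cycle_basis(toy_net)
        sf = [
            sign_pattern(toy_net, sol.r)[rid] for rid in basis.reaction_ids
        ]
        for k in range(basis.dimension):
            sc = np.sign(np.round(basis.K[:, k], 12)).astype(int)
            lhs, rhs, passes = sign_loop_test(sc, sf)
            assert passes

    def test_dg_times_flux_negative_for_running_reactions(self, toy_net):
        sol = loopless_fba(toy_net, Objective.maximize("r3"), fixed={"r0": 1.0})
        for i, rid in enumerate(sol.meta["internal_ids"]):
            flux = sol[rid]
            if abs(flux) > 1e-6:
                assert sol.dg[i] * flux < 0

    def test_loop_law_holds_on_dg(self, toy_net):
        sol = loopless_fba(toy_net, Objective.maximize("r3"), fixed={"r0": 1.0})
        K = internal_cycle_basis(toy_net).K
        assert np.max(np.abs(K.T @ sol.dg)) < 1e-6

    def test_cycle_free_network_equals_plain_fba(self, chain_net):
        obj = Objective.maximize("out")
        plain = solve_fba(chain_net, obj, fixed={"in": 1.0})
        sol = loopless_fba(chain_net, obj, fixed={"in": 1.0})
        assert sol.objective_value == pytest.approx(plain.objective_value)

    def test_never_beats_plain_fba(self, toy_net):
        for rid in ("r3", "r5"):
            plain = solve_fba(
                toy_net, Objective.maximize(rid), fixed={"r0": 1.0}
            )
            sol = loopless_fba(
                toy_net, Objective.maximize(rid), fixed={"r0": 1.0}
            )
            assert sol.objective_value <= plain.objective_value + 1e-6

    def test_bad_config_rejected(self):
        with pytest.raises(ValueError):
            LooplessConfig(big_M=0.05, epsilon=0.1)


@pytest.fixture
def consistent_spec(toy_net):
    return ThermoSpec(
        dg0_prime={
            "r1": -10.0,
            "r2": dg0_from_keq(2.0),
            "r3": dg0_from_keq(3.0),
            "r4": dg0_from_keq(18.0),
        }
    )


class TestConcentrationCoupling:
    def test_in_cycle_pattern_is_infeasible(self, toy_net, consistent_spec):
        # r2 > 0, r3 > 0, r4 < 0 runs around the cycle: no concentration
        # vector can support it
        signs = {"r1": 1, "r2": 1, "r3": 1, "r4": -1}
        sol = tfba_with_concentrations(
            toy_net,
            Objective.maximize("r3"),
            consistent_spec,
            signs,
            fixed={"r0": 1.0},
        )
        assert sol.status == "infeasible"
        assert set(sol.meta["violated_cycle"]["reactions"]) == {
            "r2",
            "r3",
            "r4",
        }

    def test_acyclic_pattern_yields_concentrations(
        self, toy_net, consistent_spec
    ):
        prior = loopless_fba(
            toy_net, Objective.maximize("r3"), fixed={"r0": 1.0}
        )
        signs = sign_pattern(toy_net, prior.r)
        sol = tfba_with_concentrations(
            toy_net,
            Objective.maximize("r3"),
            consistent_spec,
            signs,
            fixed={"r0": 1.0},
        )
        assert sol.ok
        assert sol.x is not None
        lo, hi = consistent_spec.x_bounds(toy_net)
        assert np.all(sol.x >= lo - 1e-9) and np.all(sol.x <= hi + 1e-9)

    def test_dg_times_flux_negative(self, toy_net, consistent_spec):
        prior = loopless_fba(
            toy_net, Objective.maximize("r3"), fixed={"r0": 1.0}
        )
        signs = sign_pattern(toy_net, prior.r)
        sol = tfba_with_concentrations(
            toy_net,
            Objective.maximize("r3"),
            consistent_spec,
            signs,
            fixed={"r0": 1.0},
        )
        for i, rid in enumerate(sol.meta["internal_ids"]):
            if abs(sol[rid]) > 1e-6:
                assert sol.dg[i] * sol[rid] < 0


class TestMdf:
    def test_single_reaction_matches_grid_oracle(self):
        net = Network(
            compounds=[Compound(id="X"), Compound(id="Y")],
            reactions=[Reaction(id="r", stoich={"X": -1, "Y": 1})],
        )
        spec = ThermoSpec(
            dg0_prime={"r": 0.0},
            x_min={"X": -1.0, "Y": -1.0},
            x_max={"X": 1.0, "Y": 1.0},
        )
        result = mdf(net, spec, {"r": 1})
        # brute-force grid over (x_X, x_Y)
        grid = np.linspace(-1, 1, 201)
        best = max(
            -(spec.RT * (y - x)) for x in grid for y in grid
        )
        assert result.ok
        assert result.B == pytest.approx(best, abs=1e-6)
        assert result.B == pytest.approx(2 * DEFAULT_RT, abs=1e-9)

    def test_improves_on_feasibility_margin(self, toy_net, consistent_spec):
        prior = loopless_fba(
            toy_net, Objective.maximize("r3"), fixed={"r0": 1.0}
        )
        signs = sign_pattern(toy_net, prior.r)
        eps = 0.1
        feasible = tfba_with_concentrations(
            toy_net,
            Objective.maximize("r3"),
            consistent_spec,
            signs,
            epsilon=eps,
            fixed={"r0": 1.0},
        )
        active = [
            i
            for i, rid in enumerate(feasible.meta["internal_ids"])
            if signs.get(rid, 0) != 0
        ]
        min_force_plain = min(abs(feasible.dg[i]) for i in active)
        result = mdf(toy_net, consistent_spec, signs)
        assert result.B >= min_force_plain - 1e-9
        assert result.B > eps

    def test_tightening_bounds_never_raises_B(self, toy_net, consistent_spec):
        signs = {"r1": 1, "r2": 1, "r3": -1, "r4": 1}
        wide = mdf(toy_net, consistent_spec, signs)
        tight_spec = ThermoSpec(
            dg0_prime=consistent_spec.dg0_prime,
            x_min={"A": math.log(1e-3)},
            x_max={"A": math.log(1e-2)},
        )
        tight = mdf(toy_net, tight_spec, signs)
        if tight.ok:
            assert tight.B <= wide.B + 1e-9

    def test_in_cycle_signs_give_nonpositive_force(
        self, toy_net, consistent_spec
    ):
        result = mdf(
            toy_net, consistent_spec, {"r1": 1, "r2": 1, "r3": 1, "r4": -1}
        )
        # the LP stays feasible (B unbounded below picks the least-bad x)
        # but no positive driving force can exist around a cycle
        assert not result.ok or result.B <= 1e-9
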