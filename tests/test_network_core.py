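"""Mass audits, rank/null space, cycles, growth rate, EFMs."""

import numpy as np
import pytest

from conftest import brute_force_efms
from selfcell import (
    Compound,
    Network,
    Reaction,
    audit_mass_conservation,
    dilution_ratio,
    enumerate_efms,
    fixture_toy_network,
    fixture_unit_network,
    generate_random_conservative_network,
    growth_rate_from_fluxes,
    internal_cycle_basis,
    minimize_total_flux,
    rank_and_nullspace,
)
from selfcell.model import ModelValidationError

CYCLE = np.array([0.0, -1.0, -2.0, 1.0])  # over (r1, r2, r3, r4)


def collinear(a, b, tol=1e-9):
    a, b = np.asarray(a, float), np.asarray(b, float)
    return np.linalg.norm(np.outer(a, b) - np.outer(b, a)) < tol


class TestMassAudit:
    def test_single_balanced_reaction(self):
        # 2A <-> B + 2C with w = (30, 20, 20): exactly closed
        net = Network(
            compounds=[
                Compound(id="A", molecular_weight=30),
                Compound(id="B", molecular_weight=20),
                Compound(id="C", molecular_weight=20),
            ],
            reactions=[Reaction(id="r1", stoich={"A": -2, "B": 1, "C": 2})],
        )
        report = audit_mass_conservation(net)
        assert report.residuals["r1"] == 0.0
        assert report.conserved

    def test_byproduct_reaction_loses_100_but_is_not_flagged(self, toy_net):
        report = audit_mass_conservation(toy_net)
        assert report.residuals["r6"] == pytest.approx(-100.0)
        assert "r6" not in report.flagged

    def test_unbalanced_internal_reaction_is_flagged(self):
        net = Network(
            compounds=[
                Compound(id="A", molecular_weight=30),
                Compound(id="B", molecular_weight=20),
            ],
            reactions=[Reaction(id="bad", stoich={"A": -1, "B": 1})],
        )
        assert audit_mass_conservation(net).flagged == ["bad"]

    def test_missing_weight_names_compound(self, toy_net):
        toy_net.compound("C").molecular_weight = None
        with pytest.raises(ModelValidationError, match="C"):
            audit_mass_conservation(toy_net)

    def test_residuals_are_linear_in_stoichiometry(self):
        w = {"A": 30.0, "B": 20.0, "C": 45.0}
        n1 = {"A": -2, "B": 1}
        n2 = {"B": -1, "C": 1}
        merged = {
            cid: 2 * n1.get(cid, 0) + 3 * n2.get(cid, 0) for cid in w
        }
        net = Network(
            compounds=[Compound(id=c, molecular_weight=v) for c, v in w.items()],
            reactions=[
                Reaction(id="n1", stoich=n1),
                Reaction(id="n2", stoich=n2),
                Reaction(id="merged", stoich=merged),
            ],
        )
        res = audit_mass_conservation(net).residuals
        assert res["merged"] == pytest.approx(2 * res["n1"] + 3 * res["n2"])


class TestRankNullspace:
    def test_toy_matrix_rank_and_kernel(self, toy_net):
        basis = rank_and_nullspace(toy_net.N)
        assert basis.rank == 4
        assert basis.dimension == 3

    @pytest.mark.parametrize("n", [1, 3, 6])
    def test_identity(self, n):
        basis = rank_and_nullspace(np.eye(n))
        assert basis.rank == n
        assert basis.dimension == 0

    def test_internal_matrix_kernel_is_printed_cycle(self, internal_net):
        basis = rank_and_nullspace(internal_net.N)
        assert basis.dimension == 1
        assert collinear(basis.K[:, 0], CYCLE)

    def test_rank_plus_kernel_equals_columns(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            m = rng.normal(size=(rng.integers(2, 6), rng.integers(2, 8)))
            if rng.random() < 0.5:  # force rank deficiency
                m[:, -1] = m[:, 0]
            basis = rank_and_nullspace(m)
            assert basis.rank + basis.dimension == m.shape[1]
            assert np.max(np.abs(m @ basis.K)) < 1e-9 if basis.dimension else True


class TestCycleBasis:
    def test_toy_cycle(self, toy_net):
        basis = internal_cycle_basis(toy_net)
        assert basis.reaction_ids == ["r1", "r2", "r3", "r4"]
        assert basis.dimension == 1
        assert collinear(basis.K[:, 0], CYCLE)

    def test_tree_network_has_no_cycles(self, chain_net):
        assert internal_cycle_basis(chain_net).dimension == 0

    def test_duplicated_column_gives_pair_cycle(self, chain_net):
        chain_net.add_reaction(
            Reaction(id="x2y_copy", stoich={"X": -1, "Y": 1}, lower_bound=0)
        )
        basis = internal_cycle_basis(chain_net)
        assert basis.dimension == 1
        assert collinear(basis.K[:, 0], [1.0, -1.0])

    def test_no_internal_reactions_is_an_error(self):
        net = Network(
            compounds=[Compound(id="A")],
            reactions=[Reaction(id="ex", stoich={"A": 1}, is_internal=False)],
        )
        with pytest.raises(ModelValidationError):
            internal_cycle_basis(net)


class TestGrowthRate:
    def test_internal_fluxes_of_conserved_network_give_zero(self):
        net = generate_random_conservative_network(5, 6, seed=3)
        rng = np.random.default_rng(0)
        for _ in range(5):
            r = rng.normal(size=6)
            assert abs(growth_rate_from_fluxes(net, r)) <= 1e-9

    def test_pure_uptake_of_150_gmol_substrate(self, toy_net):
        # 10 mmol/gDW/h in, nothing out: mu = 10 * 150 / 1000 = 1.5 1/h
        r = np.array([10.0, 0, 0, 0, 0, 0, 0])
        assert growth_rate_from_fluxes(toy_net, r) == pytest.approx(1.5)

    def test_two_unit_growth_is_uptake_minus_overflow(self):
        net, _ = fixture_unit_network("two-unit")
        wA = net.compound("A").molecular_weight
        rng = np.random.default_rng(1)
        for _ in range(5):
            r = rng.uniform(0, 2, size=4)
            mu = growth_rate_from_fluxes(net, r)
            assert mu == pytest.approx(wA * (r[0] - r[1]) / 1000.0)

    def test_byproduct_mass_loss_reduces_growth(self, toy_net):
        # r6 loses 100 g/mol: 2A (300 g) -> D (200 g)
        r = np.array([0.0, 0, 0, 0, 0, 0, 1.0])
        assert growth_rate_from_fluxes(toy_net, r) == pytest.approx(-0.1)

    def test_dimension_mismatch(self, toy_net):
        with pytest.raises(ValueError):
            growth_rate_from_fluxes(toy_net, np.ones(3))


class TestDilutionRatio:
    def test_glucose_example(self):
        assert dilution_ratio(6.0, 0.5, 0.03) == pytest.approx(400.0)

    def test_unit_ratio(self):
        assert dilution_ratio(1.0, 1.0, 1.0) == 1.0

    def test_joint_scaling_invariance(self):
        base = dilution_ratio(6.0, 0.5, 0.03)
        for lam in (0.1, 2.0, 17.0):
            assert dilution_ratio(6.0 * lam, 0.5, 0.03 * lam) == pytest.approx(
                base
            )

    @pytest.mark.parametrize("args", [(0, 1, 1), (1, 0, 1), (1, 1, 0)])
    def test_nonpositive_inputs_rejected(self, args):
        with pytest.raises(ValueError):
            dilution_ratio(*args)


class TestElementaryFluxModes:
    def test_toy_modes_match_brute_force_oracle(self, toy_net):
        efms = enumerate_efms(toy_net)
        oracle = brute_force_efms(toy_net)
        oracle_supports = {
            frozenset(np.flatnonzero(np.abs(m) > 1e-9)) for m in oracle
        }
        ids = toy_net.reaction_ids
        found = {
            frozenset(ids.index(r) for r in s) for s in efms.supports()
        }
        assert found == oracle_supports

    def test_single_chain_has_one_mode(self, chain_net):
        efms = enumerate_efms(chain_net)
        assert len(efms) == 1
        np.testing.assert_allclose(efms.modes[0], [1.0, 1.0, 1.0])

    def test_modes_are_steady_state_and_sign_feasible(self, toy_net):
        N = toy_net.N
        lb, _ = toy_net.bounds()
        for mode in enumerate_efms(toy_net).modes:
            assert np.max(np.abs(N @ mode)) < 1e-9
            for j, lo in enumerate(lb):
                if lo >= 0:
                    assert mode[j] >= -1e-9

    def test_supports_are_pairwise_minimal(self, toy_net):
        supports = enumerate_efms(toy_net).supports()
        for a in supports:
            for b in supports:
                assert not (a < b)

    def test_min_total_flux_support_is_a_mode(self, toy_net):
        sol = minimize_total_flux(toy_net, fixed={"r0": 1.0})
        assert sol.support() in enumerate_efms(toy_net).supports()

    @pytest.mark.parametrize("seed", [0, 2, 5])
    def test_random_networks_match_oracle(self, seed):
        net = generate_random_conservative_network(3, 5, seed=seed)
        efms = enumerate_efms(net)
        oracle = brute_force_efms(net)
        assert len(efms) == len(oracle)

    def test_size_guard(self):
        net = generate_random_conservative_network(4, 21, seed=0)
        with pytest.raises(ValueError, match="too large"):
            enumerate_efms(net)
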