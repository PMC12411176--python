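"""Self-contained growth optimization.

A self-contained cell model receives only the environment's substrate
concentration.  Metabolic fluxes follow from enzyme kinetics r_i(E_i, c),
macromolecular units are synthesized against growth dilution
(r_syn,j = mu B_j), the ribosome-like unit B2 gates all synthesis through
f_M = M/K_M, and mass closes: metabolites + B1 (incl. enzyme mass) + B2 +
B3 = 1 g/g.  Growth maximization over the enzyme, metabolite and unit
allocations is a smooth NLP, solved all-at-once (SLSQP) with multistart;
every accepted solution is re-verified independently of the solver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .kinetics import KineticLaw, reversible_rate
from .macro_units import UnitModel
from .model import Network
from .network_core import enumerate_efms, growth_rate_from_fluxes
from .solution import INFEASIBLE, OPTIMAL, FluxSolution

__all__ = [
    "SelfContainedModel",
    "NodeBalance",
    "default_selfcontained_model",
    "solve_selfcontained",
    "verify_solution",
    "substrate_sweep",
    "supply_demand",
    "compare_to_efms",
]


@dataclass
class SelfContainedModel:
    """A kinetics-driven, enzyme- and mass-budgeted cell model.

    ``network`` carries the metabolites and the macromolecular units with
    their drain reactions; ``laws`` maps each metabolic reaction to its
    rate law (the uptake reaction's substrate is the external pool "S").
    Mass closure: C_total + B1 (= b1_fixed + enzyme mass) + B2 + B3 = 1.
    """

    network: Network
    units: UnitModel
    laws: dict[str, KineticLaw]
    uptake_reaction: str = "r0"
    E_total: float = 1e-5  # mmol/gDW
    C_total: float = 0.1  # g/g
    b1_fixed: float = 0.1  # g/g of B1 besides the enzymes
    enzyme_weight: float = 1e4  # g/mol, monomer-aggregate default
    conc_floor: float = 1e-6  # mmol/gDW, a concentration cannot be zero
    conc_max: float = 1.0  # must leave the 10% mass budget reachable
    drain_prefix: str = "syn_"

    def __post_init__(self) -> None:
        for rid in self.laws:
            self.network.reaction(rid)  # raises for unknown ids

    # -- structure ------------------------------------------------------

    @property
    def metabolic_ids(self) -> list[str]:
        return [r.id for r in self.network.reactions if r.id in self.laws]

    @property
    def metabolite_ids(self) -> list[str]:
        unit_ids = {u.id for u in self.units.units}
        return [c.id for c in self.network.compounds if c.id not in unit_ids]

    @property
    def drain_ids(self) -> dict[str, str]:
        """unit id -> drain reaction id."""
        out = {}
        for u in self.units.units:
            rid = f"{self.drain_prefix}{u.id}"
            self.network.reaction(rid)
            out[u.id] = rid
        return out

    def unit_weight(self, uid: str) -> float:
        return float(self.network.compound(uid).molecular_weight)

    @property
    def gating_unit(self):
        for u in self.units.units:
            if u.gating == "self":
                return u
        return None

    # -- evaluation -----------------------------------------------------

    def metabolic_fluxes(
        self, E: Mapping[str, float], conc: Mapping[str, float], S_ext: float
    ) -> dict[str, float]:
        """Kinetic rates r_i(E_i, c) for every metabolic reaction."""
        rates = {}
        for rid in self.metabolic_ids:
            law = self.laws[rid]
            if rid == self.uptake_reaction:
                pools: Mapping[str, float] = {"S": S_ext, **conc}
            else:
                pools = conc
            rates[rid] = reversible_rate(law, E[rid], pools, pools)
        return rates

    def growth_rate(self, rates: Mapping[str, float]) -> float:
        """mu = w^T N r / 1000 over the metabolic columns (the unit drains
        are mass conservative and contribute nothing)."""
        weights = {c.id: c.molecular_weight for c in self.network.compounds}
        mu = 0.0
        for rid, r in rates.items():
            rxn = self.network.reaction(rid)
            mu += r * sum(
                coef * weights[cid] for cid, coef in rxn.stoich.items()
            )
        return mu / 1000.0

    def allocation(self, E: Mapping[str, float], B2: float) -> dict[str, float]:
        """Mass fractions of the closure set {C, B1, B2, B3}."""
        e_mass = sum(E.values()) * self.enzyme_weight / 1000.0
        B1 = self.b1_fixed + e_mass
        B3 = 1.0 - self.C_total - B1 - B2
        return {
            "C": self.C_total,
            "B1": B1,
            "B2": B2,
            "B3": B3,
            "E_mass": e_mass,
        }

    def drain_rates(
        self, mu: float, alloc: Mapping[str, float]
    ) -> dict[str, float]:
        """Molar unit-synthesis rates balancing dilution, mmol/gDW/h."""
        out = {}
        for u in self.units.units:
            B = alloc[u.id]
            out[self.drain_ids[u.id]] = 1000.0 * mu * B / self.unit_weight(u.id)
        return out

    def full_flux_vector(
        self, rates: Mapping[str, float], drains: Mapping[str, float]
    ) -> np.ndarray:
        r = np.zeros(len(self.network.reactions))
        for rid, v in {**rates, **drains}.items():
            r[self.network.reaction_index(rid)] = v
        return r

    def steady_state_residuals(
        self,
        rates: Mapping[str, float],
        drains: Mapping[str, float],
        conc: Mapping[str, float],
        mu: float,
    ) -> np.ndarray:
        """d c_j/dt = (N r)_j - mu c_j for every metabolite (mmol/gDW/h)."""
        r = self.full_flux_vector(rates, drains)
        N = self.network.stoichiometric_matrix
        prod = N @ r
        out = []
        for cid in self.metabolite_ids:
            j = self.network.compound_index(cid)
            out.append(prod[j] - mu * conc[cid])
        return np.array(out)


@dataclass
class NodeBalance:
    """Supply/demand decomposition of one metabolite's steady state.

    supply: reactions producing the metabolite (flow > 0, mmol/gDW/h);
    demand: reactions consuming it; biomass_drain: consumption by unit
    synthesis; dilution: mu * c.  At steady state
    sum(supply) - sum(demand) - biomass_drain - dilution = 0.
    """

    metabolite: str
    supply: dict[str, float]
    demand: dict[str, float]
    biomass_drain: float
    dilution: float

    @property
    def residual(self) -> float:
        return (
            sum(self.supply.values())
            - sum(self.demand.values())
            - self.biomass_drain
            - self.dilution
        )


def default_selfcontained_model(
    E_total: float = 1e-5,
    C_total: float = 0.1,
    b1_fixed: float = 0.1,
    kcat: float = 1.8e6,
    K_bind: float = 0.01,
) -> SelfContainedModel:
    """The three-unit reference model with documented kinetic defaults.

    Binding constants sit mid-window (0.01 mmol/gDW); equilibrium
    constants drive the network downhill from A to D and satisfy the
    cycle identity K_eq4 = K_eq2 * K_eq3^2.
    """
    from .fixtures import fixture_unit_network

    net, units = fixture_unit_network("three-unit")
    ks = K_bind
    keq2, keq3 = 1e4, 10.0
    laws = {
        "r0": KineticLaw(kcat=kcat, Ks={"S": 1.0}),
        "r1": KineticLaw(
            kcat=kcat,
            Ks={"A": ks},
            Kp={"B": ks, "C": ks},
            orders={"A": 2, "B": 1, "C": 2},
            k_eq=10.0,
        ),
        "r2": KineticLaw(
            kcat=kcat, Ks={"B": ks}, Kp={"D": ks}, orders={"B": 2}, k_eq=keq2
        ),
        "r3": KineticLaw(kcat=kcat, Ks={"C": ks}, Kp={"B": ks}, k_eq=keq3),
        "r4": KineticLaw(
            kcat=kcat,
            Ks={"C": ks},
            Kp={"D": ks},
            orders={"C": 2},
            k_eq=keq2 * keq3**2,
        ),
        "r5": KineticLaw(kcat=kcat, Ks={"D": ks}),
        "r6": KineticLaw(kcat=kcat, Ks={"A": ks}, orders={"A": 2}),
    }
    return SelfContainedModel(
        network=net,
        units=units,
        laws=laws,
        E_total=E_total,
        C_total=C_total,
        b1_fixed=b1_fixed,
    )


# ---------------------------------------------------------------------------
# Solver
# ---------------------------------------------------------------------------


def _evaluate(model: SelfContainedModel, u: np.ndarray, S_ext: float):
    """Unpack scaled decision variables and evaluate the cell state.

    u = [e_i (enzyme shares), psi_j (metabolite mass shares), B2].
    """
    n_e = len(model.metabolic_ids)
    mets = model.metabolite_ids
    e = u[:n_e]
    psi = u[n_e : n_e + len(mets)]
    B2 = float(u[-1])
    E = {rid: float(e[i]) * model.E_total for i, rid in enumerate(model.metabolic_ids)}
    weights = {c.id: c.molecular_weight for c in model.network.compounds}
    conc = {
        cid: 1000.0 * model.C_total * float(psi[j]) / weights[cid]
        for j, cid in enumerate(mets)
    }
    rates = model.metabolic_fluxes(E, conc, S_ext)
    mu = model.growth_rate(rates)
    alloc = model.allocation(E, B2)
    drains = model.drain_rates(max(mu, 0.0), alloc)
    res = model.steady_state_residuals(rates, drains, conc, mu)
    return E, conc, rates, mu, alloc, drains, res, psi


def _variable_bounds(
    model: SelfContainedModel,
) -> tuple[np.ndarray, np.ndarray]:
    n_e = len(model.metabolic_ids)
    mets = model.metabolite_ids
    weights = {c.id: c.molecular_weight for c in model.network.compounds}
    psi_floor = [
        model.conc_floor * weights[cid] / (1000.0 * model.C_total) for cid in mets
    ]
    psi_ceil = [
        min(1.0, model.conc_max * weights[cid] / (1000.0 * model.C_total))
        for cid in mets
    ]
    lo = np.concatenate([np.zeros(n_e), psi_floor, [0.0]])
    hi = np.concatenate(
        [np.ones(n_e), psi_ceil, [1.0 - model.C_total - model.b1_fixed]]
    )
    return lo, hi


def _start_points(
    model: SelfContainedModel, starts: int, seed: int
) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    n_e = len(model.metabolic_ids)
    n_m = len(model.metabolite_ids)
    pts = []
    # one structured start: uptake-heavy enzymes, even metabolites
    e0 = np.full(n_e, 0.5 / n_e)
    e0[model.metabolic_ids.index(model.uptake_reaction)] = 0.4
    pts.append(np.concatenate([e0, np.full(n_m, 1.0 / n_m), [0.3]]))
    for _ in range(max(0, starts - 1)):
        e = rng.dirichlet(np.ones(n_e)) * rng.uniform(0.5, 1.0)
        psi = rng.dirichlet(np.ones(n_m))
        b2 = rng.uniform(0.05, 0.6)
        pts.append(np.concatenate([e, psi, [b2]]))
    return pts


def _penalized_residuals(
    model: SelfContainedModel,
    u: np.ndarray,
    S_ext: float,
    mu_target: float | None,
) -> np.ndarray:
    """Steady state + budget-closure system as a least-squares vector.

    Inequality budgets enter as one-sided penalties; pinning mu turns
    growth maximization into a feasibility ladder over mu targets.
    """
    n_e = len(model.metabolic_ids)
    E, conc, rates, mu, alloc, _, res, psi = _evaluate(model, u, S_ext)
    pen = [
        np.sum(psi) - 1.0,
        10.0 * max(0.0, np.sum(u[:n_e]) - 1.0),
        10.0 * max(0.0, -alloc["B3"]),
    ]
    gate = model.gating_unit
    if gate is not None:
        f_m = conc[gate.gating_metabolite] / gate.k_m
        cap = gate.k_syn * f_m * alloc["B2"] - mu * (alloc["B1"] + alloc["B2"])
        pen.append(10.0 * max(0.0, -cap))
    if mu_target is not None:
        pen.append(10.0 * (mu - mu_target))
    return np.concatenate([res, pen])


def _feasibility_solve(
    model: SelfContainedModel,
    u0: np.ndarray,
    S_ext: float,
    mu_target: float | None,
    lo: np.ndarray,
    hi: np.ndarray,
) -> tuple[bool, np.ndarray]:
    res = optimize.least_squares(
        lambda u: _penalized_residuals(model, u, S_ext, mu_target),
        np.clip(u0, lo, hi),
        bounds=(lo, hi),
        xtol=1e-13,
        ftol=1e-13,
        max_nfev=400,
    )
    ok = bool(
        np.max(np.abs(_penalized_residuals(model, res.x, S_ext, mu_target)))
        < 1e-6
    )
    return ok, res.x


def _growth_ladder(
    model: SelfContainedModel,
    u0: np.ndarray,
    S_ext: float,
    lo: np.ndarray,
    hi: np.ndarray,
    step: float = 0.3,
    bisections: int = 10,
) -> tuple[float, np.ndarray] | None:
    """Push the feasible growth rate up: coarse ladder then bisection."""
    ok, u = _feasibility_solve(model, u0, S_ext, None, lo, hi)
    if not ok:
        return None
    best_mu = _evaluate(model, u, S_ext)[3]
    best = (max(best_mu, 0.0), u)
    target = best[0] + step
    while True:
        ok, u_new = _feasibility_solve(model, best[1], S_ext, target, lo, hi)
        if not ok:
            break
        best = (target, u_new)
        target += step
    lo_t, hi_t = best[0], best[0] + step
    for _ in range(bisections):
        mid = 0.5 * (lo_t + hi_t)
        ok, u_new = _feasibility_solve(model, best[1], S_ext, mid, lo, hi)
        if ok:
            best = (mid, u_new)
            lo_t = mid
        else:
            hi_t = mid
    return best


def _slsqp_polish(
    model: SelfContainedModel,
    u0: np.ndarray,
    S_ext: float,
    lo: np.ndarray,
    hi: np.ndarray,
) -> np.ndarray | None:
    n_e = len(model.metabolic_ids)
    gate = model.gating_unit

    def eq_constraints(u):
        _, _, _, _, _, _, res, psi = _evaluate(model, u, S_ext)
        return np.concatenate([[np.sum(psi) - 1.0], res])

    def ineq_constraints(u):
        E, conc, _, mu, alloc, _, _, _ = _evaluate(model, u, S_ext)
        out = [1.0 - np.sum(u[:n_e]), alloc["B3"]]
        if gate is not None:
            f_m = conc[gate.gating_metabolite] / gate.k_m
            out.append(
                gate.k_syn * f_m * alloc["B2"] - mu * (alloc["B1"] + alloc["B2"])
            )
        return np.array(out)

    res = optimize.minimize(
        lambda u: -_evaluate(model, u, S_ext)[3],
        u0,
        method="SLSQP",
        bounds=list(zip(lo, hi)),
        constraints=[
            {"type": "eq", "fun": eq_constraints},
            {"type": "ineq", "fun": ineq_constraints},
        ],
        options={"maxiter": 200, "ftol": 1e-12},
    )
    return res.x if res.success else None


def solve_selfcontained(
    model: SelfContainedModel,
    S_ext: float,
    starts: int = 4,
    seed: int = 0,
    extra_starts: Sequence[np.ndarray] = (),
) -> FluxSolution:
    """Maximize growth over enzyme, metabolite and unit allocations.

    For each start a feasible steady state is found by damped least
    squares, the growth rate is pushed up along a feasibility ladder
    (bisection on pinned mu targets), and the best point is polished by a
    constrained SLSQP step.  Every candidate is re-verified by
    ``verify_solution`` before acceptance; the manifest logs all starts.
    """
    lo, hi = _variable_bounds(model)
    log = []
    best: tuple[np.ndarray, float] | None = None
    for k, u0 in enumerate(list(extra_starts) + _start_points(model, starts, seed)):
        out = _growth_ladder(model, u0, S_ext, lo, hi)
        entry: dict = {"start": k, "reached": None}
        if out is not None:
            mu_k, u_k = out
            checks = verify_solution(model, u_k, S_ext)
            entry.update(reached=mu_k, verified=checks["ok"])
            if checks["ok"] and (best is None or mu_k > best[1]):
                best = (u_k, mu_k)
        log.append(entry)
    if best is not None:
        polished = _slsqp_polish(model, best[0], S_ext, lo, hi)
        if polished is not None:
            mu_p = _evaluate(model, polished, S_ext)[3]
            if mu_p > best[1] and verify_solution(model, polished, S_ext)["ok"]:
                best = (polished, mu_p)
                log.append({"start": "polish", "reached": mu_p, "verified": True})
    if best is None:
        diagnostics = {
            "starts": log,
            "hint": "no start reached a verified steady state",
        }
        return FluxSolution(
            reaction_ids=model.network.reaction_ids,
            r=None,
            objective_value=None,
            status=INFEASIBLE,
            meta=diagnostics,
        )
    u, mu = best
    E, conc, rates, mu_val, alloc, drains, res_vec, _ = _evaluate(model, u, S_ext)
    weights = {c.id: c.molecular_weight for c in model.network.compounds}
    r = model.full_flux_vector(rates, drains)
    enzymes = np.array([E[rid] for rid in model.metabolic_ids])
    x = np.array(
        [
            math.log(conc[c.id])
            if c.id in conc
            else math.log(
                1000.0 * alloc.get(c.id, alloc["B3"]) / weights[c.id]
            )
            for c in model.network.compounds
        ]
    )
    return FluxSolution(
        reaction_ids=model.network.reaction_ids,
        r=r,
        objective_value=mu_val,
        status=OPTIMAL,
        mu=mu_val,
        x=x,
        enzymes=enzymes,
        meta={
            "solver": "lsq-ladder+slsqp",
            "S_ext": S_ext,
            "allocation": alloc,
            "concentrations": conc,
            "enzyme_ids": model.metabolic_ids,
            "decision_vector": u.tolist(),
            "starts": log,
            "residuals": res_vec.tolist(),
        },
    )


def verify_solution(
    model: SelfContainedModel,
    u: np.ndarray,
    S_ext: float,
    tol: float = 1e-5,
) -> dict:
    """Re-check a candidate state without trusting the solver.

    Recomputes every kinetic rate, the growth rate, the steady-state
    residuals, budget constraints and the mass closure from the raw
    decision vector.
    """
    E, conc, rates, mu, alloc, drains, res, psi = _evaluate(model, u, S_ext)
    scale = max(1.0, max(abs(v) for v in rates.values()))
    checks = {
        "steady_state": bool(np.max(np.abs(res)) <= tol * scale),
        "metabolite_budget": bool(
            abs(
                sum(
                    conc[cid] * model.network.compound(cid).molecular_weight
                    for cid in conc
                )
                / 1000.0
                - model.C_total
            )
            <= 1e-6
        ),
        "enzyme_budget": bool(sum(E.values()) <= model.E_total * (1 + 1e-9)),
        "closure": bool(
            abs(
                alloc["C"] + alloc["B1"] + alloc["B2"] + alloc["B3"] - 1.0
            )
            <= 1e-9
        ),
        "B3_nonnegative": bool(alloc["B3"] >= -1e-9),
        "mu_consistent": bool(
            abs(
                growth_rate_from_fluxes(
                    model.network, model.full_flux_vector(rates, drains)
                )
                - mu
            )
            <= 1e-6 * max(1.0, abs(mu))
        ),
    }
    gate = model.gating_unit
    if gate is not None:
        f_m = conc[gate.gating_metabolite] / gate.k_m
        checks["gating_capacity"] = bool(
            gate.k_syn * f_m * alloc["B2"]
            >= mu * (alloc["B1"] + alloc["B2"]) - tol
        )
    checks["ok"] = all(checks.values())
    checks["mu"] = mu
    return checks


def substrate_sweep(
    model: SelfContainedModel,
    S_values: Sequence[float],
    starts: int = 9,
    seed: int = 0,
) -> pd.DataFrame:
    """Solve across substrate levels with warm starts.

    Yield is biomass formed per substrate mass consumed,
    1000 * mu / (w_S * r_uptake).
    """
    rows = []
    warm: list[np.ndarray] = []
    w_s = model.network.compound("A").molecular_weight
    for S in S_values:
        sol = solve_selfcontained(
            model, S, starts=starts, seed=seed, extra_starts=warm
        )
        if not sol.ok:
            rows.append({"S": S, "status": sol.status})
            continue
        warm = [np.array(sol.meta["decision_vector"])]
        uptake = sol[model.uptake_reaction]
        alloc = sol.meta["allocation"]
        rows.append(
            {
                "S": S,
                "status": sol.status,
                "mu": sol.mu,
                "uptake": uptake,
                "yield": 1000.0 * sol.mu / (w_s * uptake) if uptake > 0 else np.nan,
                "B1": alloc["B1"],
                "B2": alloc["B2"],
                "B3": alloc["B3"],
                "E_mass": alloc["E_mass"],
            }
        )
    return pd.DataFrame(rows)


def supply_demand(
    model: SelfContainedModel,
    solution: FluxSolution,
    metabolite: str,
) -> NodeBalance:
    """Partition one metabolite's steady-state equation into supply,
    demand, biomass drain and dilution terms."""
    if metabolite not in model.metabolite_ids:
        raise KeyError(f"unknown metabolite {metabolite!r}")
    drains = set(model.drain_ids.values())
    supply: dict[str, float] = {}
    demand: dict[str, float] = {}
    biomass = 0.0
    for rxn in model.network.reactions:
        coef = rxn.stoich.get(metabolite)
        if coef is None:
            continue
        flow = coef * solution[rxn.id]
        if abs(flow) < 1e-12:
            continue
        if rxn.id in drains:
            biomass += -flow
        elif flow > 0:
            supply[rxn.id] = flow
        else:
            demand[rxn.id] = -flow
    conc = solution.meta.get("concentrations", {})
    dilution = (solution.mu or 0.0) * conc.get(metabolite, 0.0)
    return NodeBalance(
        metabolite=metabolite,
        supply=supply,
        demand=demand,
        biomass_drain=biomass,
        dilution=dilution,
    )


def compare_to_efms(
    model: SelfContainedModel,
    solutions: Sequence[FluxSolution],
    uptake: str | None = None,
) -> pd.DataFrame:
    """Place solutions against the network's elementary flux modes.

    Units are treated as drains (their rows unbalanced), matching the
    biomass-building modes; each EFM is scaled to the solution's uptake
    flux and the nearest mode reported by normalized distance over the
    metabolic fluxes.
    """
    uptake = uptake or model.uptake_reaction
    net = model.network.copy()
    for u in model.units.units:
        net.compound(u.id).is_external = True
    efms = enumerate_efms(net)
    met_idx = [net.reaction_index(rid) for rid in model.metabolic_ids]
    up_idx = net.reaction_index(uptake)
    rows = []
    for k, sol in enumerate(solutions):
        r = np.asarray(sol.r)
        r_up = r[up_idx]
        best = (np.inf, None)
        for m, mode in enumerate(efms.modes):
            if abs(mode[up_idx]) < 1e-9:
                continue
            scaled = mode * (r_up / mode[up_idx])
            d = np.linalg.norm(r[met_idx] - scaled[met_idx]) / max(
                np.linalg.norm(r[met_idx]), 1e-12
            )
            if d < best[0]:
                best = (d, m)
        rows.append(
            {
                "solution": k,
                "mu": sol.mu
                if sol.mu is not None
                else growth_rate_from_fluxes(model.network, r),
                "total_flux": float(np.sum(np.abs(r[met_idx]))),
                "nearest_efm": best[1],
                "distance": best[0],
                "n_efms": len(efms),
            }
        )
    return pd.DataFrame(rows)
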