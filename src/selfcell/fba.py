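"""Flux balance analysis: LP objectives, total-flux minimization and
two-objective Pareto fronts.

All programs share the steady-state constraint N r = 0 over the (non
external) compound rows, the per-reaction bounds, and optional fixed
(measured) fluxes.  Solved with the HiGHS solvers behind
scipy.optimize.linprog.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
from scipy import optimize

from .model import Network
from .solution import INFEASIBLE, OPTIMAL, UNBOUNDED, FluxSolution, Objective

__all__ = ["solve_fba", "minimize_total_flux", "pareto_front", "evaluate_objective"]

_STATUS = {0: OPTIMAL, 2: INFEASIBLE, 3: UNBOUNDED}

#: feasibility tolerance asserted on returned solutions
FEAS_TOL = 1e-8


def _balance_rows(net: Network) -> np.ndarray:
    """Mass-balance rows: every compound not marked external."""
    N = net.stoichiometric_matrix
    keep = [i for i, c in enumerate(net.compounds) if not c.is_external]
    return N[keep, :]


def _apply_fixed(
    net: Network, fixed: Mapping[str, float] | None
) -> list[tuple[float, float]]:
    lb, ub = net.bounds()
    bounds = list(zip(lb, ub))
    for rid, value in (fixed or {}).items():
        j = net.reaction_index(rid)
        if not lb[j] - FEAS_TOL <= value <= ub[j] + FEAS_TOL:
            raise ValueError(
                f"fixed value {value} for {rid!r} outside bounds "
                f"[{lb[j]}, {ub[j]}]"
            )
        bounds[j] = (value, value)
    return bounds


def growth_coefficients(net: Network) -> np.ndarray:
    """Per-reaction contribution to mu = w^T N r / 1000 (1/h).

    On a fully balanced network w^T N r vanishes identically, so growth is
    accounted through the rows exempt from balancing: mass flowing into
    external biomass/unit compounds, plus mass drained by biomass-style
    pseudo-reactions (non-internal, ``allows_mass_loss``, no products —
    the convention of :func:`selfcell.macro_units.biomass_pseudoreaction`).
    """
    weights = {c.id: c.molecular_weight for c in net.compounds}
    external = {c.id for c in net.compounds if c.is_external}
    g = np.zeros(len(net.reactions))
    for j, rxn in enumerate(net.reactions):
        for cid, coef in rxn.stoich.items():
            if cid in external:
                g[j] += coef * weights[cid] / 1000.0
        is_drain = (
            not rxn.is_internal
            and rxn.allows_mass_loss
            and all(coef <= 0 for coef in rxn.stoich.values())
        )
        if is_drain:
            g[j] += -sum(
                coef * weights[cid] for cid, coef in rxn.stoich.items()
            ) / 1000.0
    return g


def evaluate_objective(net: Network, obj: Objective, r: np.ndarray) -> float:
    """Value of an objective at a flux vector (natural orientation)."""
    if obj.kind == "total_flux":
        return float(np.sum(np.abs(r)))
    if obj.kind == "growth":
        return float(growth_coefficients(net) @ r)
    return float(obj.vector(net.reaction_ids) @ r)


def _objective_vector(net: Network, obj: Objective) -> np.ndarray:
    if obj.kind == "growth":
        return growth_coefficients(net)
    if obj.kind != "total_flux":
        return obj.vector(net.reaction_ids)
    raise ValueError("total_flux objective requires the split formulation")


def solve_fba(
    net: Network,
    obj: Objective,
    fixed: Mapping[str, float] | None = None,
    tie_break: bool = True,
) -> FluxSolution:
    """Optimize a linear objective over the steady-state flux polytope.

    Degenerate optima are tie-broken (``tie_break``) by a secondary
    minimization of the total flux at the optimal objective value, so
    results are reproducible; detected degeneracy is flagged in
    ``meta["degenerate"]``.
    """
    if obj.kind == "total_flux":
        return minimize_total_flux(net, fixed=fixed)
    c = _objective_vector(net, obj)
    sign = -1.0 if obj.sense == "max" else 1.0
    A_eq = _balance_rows(net)
    bounds = _apply_fixed(net, fixed)
    res = optimize.linprog(
        sign * c,
        A_eq=A_eq,
        b_eq=np.zeros(A_eq.shape[0]),
        bounds=bounds,
        method="highs",
    )
    status = _STATUS.get(res.status, INFEASIBLE)
    if status != OPTIMAL:
        return FluxSolution(
            reaction_ids=net.reaction_ids,
            r=None,
            objective_value=None,
            status=status,
            meta={"solver": "highs"},
        )
    r = np.asarray(res.x)
    objective_value = float(c @ r)
    meta: dict = {"solver": "highs", "sense": obj.sense}
    if tie_break:
        r2 = _min_total_flux_at(net, bounds, c, objective_value)
        if r2 is not None:
            primary_sum = float(np.sum(np.abs(r)))
            secondary_sum = float(np.sum(np.abs(r2)))
            meta["degenerate"] = secondary_sum < primary_sum - 1e-6 * max(
                1.0, primary_sum
            )
            r = r2
    return FluxSolution(
        reaction_ids=net.reaction_ids,
        r=r,
        objective_value=objective_value,
        status=OPTIMAL,
        meta=meta,
    )


def _split_problem(
    net: Network, bounds: list[tuple[float, float]]
) -> tuple[np.ndarray, list[tuple[float, float]], np.ndarray]:
    """Forward/backward split: r = f - b with f, b >= 0.

    Returns (equality matrix over [f, b], bounds, recombination matrix).
    """
    q = len(net.reactions)
    A = _balance_rows(net)
    A_eq = np.hstack([A, -A])
    split_bounds: list[tuple[float, float]] = []
    for lo, hi in bounds:
        split_bounds.append((max(lo, 0.0), max(hi, 0.0)))  # forward part
    for lo, hi in bounds:
        split_bounds.append((max(-hi, 0.0), max(-lo, 0.0)))  # backward part
    recomb = np.hstack([np.eye(q), -np.eye(q)])
    return A_eq, split_bounds, recomb


def _min_total_flux_at(
    net: Network,
    bounds: list[tuple[float, float]],
    c: np.ndarray,
    value: float,
) -> np.ndarray | None:
    """Lexicographic step: minimize sum |r| with c @ r pinned to value."""
    q = len(net.reactions)
    A_eq, split_bounds, recomb = _split_problem(net, bounds)
    A_eq = np.vstack([A_eq, c @ recomb])
    b_eq = np.zeros(A_eq.shape[0])
    b_eq[-1] = value
    res = optimize.linprog(
        np.ones(2 * q),
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=split_bounds,
        method="highs",
    )
    if res.status != 0:
        return None
    return recomb @ np.asarray(res.x)


def minimize_total_flux(
    net: Network,
    fixed: Mapping[str, float] | None = None,
    floor_mu: float | None = None,
) -> FluxSolution:
    """Minimize sum |r_i| via the forward/backward split.

    ``floor_mu`` adds w^T N r / 1000 >= floor_mu, keeping a minimum growth
    rate while pruning futile flux.
    """
    q = len(net.reactions)
    bounds = _apply_fixed(net, fixed)
    A_eq, split_bounds, recomb = _split_problem(net, bounds)
    A_ub = None
    b_ub = None
    if floor_mu is not None:
        mu_row = growth_coefficients(net) @ recomb
        A_ub = -mu_row[None, :]
        b_ub = np.array([-floor_mu])
    res = optimize.linprog(
        np.ones(2 * q),
        A_eq=A_eq,
        b_eq=np.zeros(A_eq.shape[0]),
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=split_bounds,
        method="highs",
    )
    status = _STATUS.get(res.status, INFEASIBLE)
    if status != OPTIMAL:
        return FluxSolution(
            reaction_ids=net.reaction_ids,
            r=None,
            objective_value=None,
            status=status,
            meta={"solver": "highs"},
        )
    r = recomb @ np.asarray(res.x)
    return FluxSolution(
        reaction_ids=net.reaction_ids,
        r=r,
        objective_value=float(np.sum(np.abs(r))),
        status=OPTIMAL,
        meta={"solver": "highs", "objective": "total_flux"},
    )


def pareto_front(
    net: Network,
    obj1: Objective,
    obj2: Objective,
    n_points: int = 20,
    fixed: Mapping[str, float] | None = None,
) -> list[tuple[float, float, FluxSolution]]:
    """Epsilon-constraint sweep between two objectives.

    obj1 is optimized while obj2 is constrained on a grid spanning from
    obj2's own optimum to its value at obj1's optimum; the endpoints of
    the returned front are the two single-objective optima.  Points are
    (value1, value2, solution), non-dominated and monotone.
    """
    if n_points < 2:
        raise ValueError("need at least two grid points")
    sol1 = solve_fba(net, obj1, fixed=fixed)
    if not sol1.ok:
        raise ValueError(f"objective 1 not solvable: status {sol1.status}")
    if obj2.kind == "total_flux":
        sol2 = minimize_total_flux(net, fixed=fixed)
    else:
        sol2 = solve_fba(net, obj2, fixed=fixed)
    if not sol2.ok:
        raise ValueError(f"objective 2 not solvable: status {sol2.status}")
    v2_at_1 = evaluate_objective(net, obj2, sol1.r)
    v2_opt = evaluate_objective(net, obj2, sol2.r)

    q = len(net.reactions)
    bounds = _apply_fixed(net, fixed)
    A_eq, split_bounds, recomb = _split_problem(net, bounds)
    c1 = _objective_vector(net, obj1) @ recomb
    sign1 = -1.0 if obj1.sense == "max" else 1.0
    if obj2.kind == "total_flux":
        c2 = np.ones(2 * q)
    else:
        c2 = _objective_vector(net, obj2) @ recomb
    sense2 = 1.0 if obj2.sense == "min" or obj2.kind == "total_flux" else -1.0

    front: list[tuple[float, float, FluxSolution]] = []
    for eps in np.linspace(v2_opt, v2_at_1, n_points):
        res = optimize.linprog(
            sign1 * c1,
            A_eq=A_eq,
            b_eq=np.zeros(A_eq.shape[0]),
            A_ub=(sense2 * c2)[None, :],
            b_ub=np.array([sense2 * eps]),
            bounds=split_bounds,
            method="highs",
        )
        if res.status != 0:
            warnings.warn(f"pareto grid point at {eps} infeasible; skipped")
            continue
        r = recomb @ np.asarray(res.x)
        v1 = evaluate_objective(net, obj1, r)
        v2 = evaluate_objective(net, obj2, r)
        front.append(
            (
                v1,
                v2,
                FluxSolution(
                    reaction_ids=net.reaction_ids,
                    r=r,
                    objective_value=v1,
                    status=OPTIMAL,
                    meta={"solver": "highs", "epsilon": float(eps)},
                ),
            )
        )
    return front
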