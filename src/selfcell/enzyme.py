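"""Enzyme-capacity constraints and enzyme-cost minimization.

Each catalyzed flux is bounded by its enzyme level, |r_i| <= kcat_i E_i,
and the enzyme pool is shared: sum E_i <= E_total.  Reversible fluxes are
handled by forward/backward splitting so all capacity inequalities act on
non-negative rates.  Utility conversions translate copy numbers per cell
into specific concentrations and back into apparent turnover numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import optimize

from .fba import _apply_fixed, _split_problem
from .model import Network
from .solution import INFEASIBLE, OPTIMAL, UNBOUNDED, FluxSolution, Objective

__all__ = [
    "AVOGADRO",
    "DEFAULT_KCAT",
    "EnzymeSpec",
    "capacity_fba",
    "enzyme_cost_min",
    "copy_number_to_conc",
    "estimate_kcat",
]

#: 1/mol
AVOGADRO = 6.022e23

#: stand-in turnover number (1/h) when a model gives none: the order of
#: magnitude estimated from ~2000 transporter copies per 1e-12 gDW cell
#: carrying 6 mmol/gDW/h
DEFAULT_KCAT = 1.8e6


@dataclass
class EnzymeSpec:
    """Turnover numbers, per-enzyme caps, the shared budget and cost weights.

    ``kcat`` (1/h) keys the reactions under capacity control; reactions
    absent from it are not enzyme-limited.  ``weights`` are the cost
    coefficients of enzyme minimization (default 1, e.g. molecular
    weights).
    """

    kcat: dict[str, float] = field(default_factory=dict)
    E_total: float = np.inf
    E_max: dict[str, float] = field(default_factory=dict)
    weights: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for rid, k in self.kcat.items():
            if k <= 0:
                raise ValueError(f"kcat for {rid!r} must be positive")
        if self.E_total <= 0:
            raise ValueError("E_total must be positive")

    @classmethod
    def for_network(
        cls,
        net: Network,
        E_total: float = np.inf,
        default_kcat: float = DEFAULT_KCAT,
    ) -> "EnzymeSpec":
        """Capacity-bound every reaction, using annotated kcat values and
        the documented stand-in default elsewhere."""
        kcat = {
            r.id: (r.kcat if r.kcat is not None else default_kcat)
            for r in net.reactions
        }
        return cls(kcat=kcat, E_total=E_total)

    def weight(self, rid: str) -> float:
        return self.weights.get(rid, 1.0)


def _capacity_program(
    net: Network,
    esp: EnzymeSpec,
    fixed: Mapping[str, float] | None,
) -> tuple[np.ndarray, list, np.ndarray, np.ndarray, list[str], np.ndarray]:
    """Shared constraint matrix over variables [f, b, E].

    Returns (A_eq rows over split fluxes, variable bounds, A_ub, b_ub,
    capacity-bound reaction ids, recombination matrix padded for E)."""
    q = len(net.reactions)
    bounds = _apply_fixed(net, fixed)
    A_eq, split_bounds, recomb = _split_problem(net, bounds)
    cap_ids = [r.id for r in net.reactions if r.id in esp.kcat]
    ne = len(cap_ids)
    nvar = 2 * q + ne
    A_eq_full = np.hstack([A_eq, np.zeros((A_eq.shape[0], ne))])
    var_bounds = list(split_bounds) + [
        (0.0, esp.E_max.get(rid, np.inf)) for rid in cap_ids
    ]
    rows = []
    rhs = []
    for k, rid in enumerate(cap_ids):
        j = net.reaction_index(rid)
        row = np.zeros(nvar)  # f_j + b_j - kcat E_k <= 0
        row[j] = 1.0
        row[q + j] = 1.0
        row[2 * q + k] = -esp.kcat[rid]
        rows.append(row)
        rhs.append(0.0)
    if np.isfinite(esp.E_total):
        row = np.zeros(nvar)
        row[2 * q :] = 1.0
        rows.append(row)
        rhs.append(esp.E_total)
    recomb_full = np.hstack([recomb, np.zeros((q, ne))])
    return (
        A_eq_full,
        var_bounds,
        np.vstack(rows),
        np.array(rhs),
        cap_ids,
        recomb_full,
    )


def _finish(
    net: Network,
    res,
    recomb: np.ndarray,
    cap_ids: list[str],
    objective_value,
    meta: dict,
) -> FluxSolution:
    status = {0: OPTIMAL, 2: INFEASIBLE, 3: UNBOUNDED}.get(res.status, INFEASIBLE)
    if status != OPTIMAL:
        return FluxSolution(
            reaction_ids=net.reaction_ids,
            r=None,
            objective_value=None,
            status=status,
            meta=meta,
        )
    x = np.asarray(res.x)
    q = len(net.reactions)
    r = recomb[:, : 2 * q] @ x[: 2 * q]
    E = x[2 * q :]
    meta = dict(meta, capacity_ids=cap_ids)
    return FluxSolution(
        reaction_ids=net.reaction_ids,
        r=r,
        objective_value=objective_value(r, E),
        status=OPTIMAL,
        enzymes=E,
        meta=meta,
    )


def capacity_fba(
    net: Network,
    obj: Objective,
    esp: EnzymeSpec,
    fixed: Mapping[str, float] | None = None,
) -> FluxSolution:
    """FBA with |r_i| <= kcat_i E_i and a shared enzyme budget.

    With an unbounded budget the constraints are slack and the optimum
    equals plain FBA; tightening E_total can only reduce the objective.
    """
    if obj.kind == "total_flux":
        raise ValueError("use enzyme_cost_min for cost-style objectives")
    from .fba import _objective_vector

    q = len(net.reactions)
    A_eq, var_bounds, A_ub, b_ub, cap_ids, recomb = _capacity_program(
        net, esp, fixed
    )
    c_r = _objective_vector(net, obj)
    cost = np.zeros(2 * q + len(cap_ids))
    cost[: 2 * q] = c_r @ recomb[:, : 2 * q]
    sign = -1.0 if obj.sense == "max" else 1.0
    res = optimize.linprog(
        sign * cost,
        A_eq=A_eq,
        b_eq=np.zeros(A_eq.shape[0]),
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=var_bounds,
        method="highs",
    )
    return _finish(
        net,
        res,
        recomb,
        cap_ids,
        lambda r, E: float(c_r @ r),
        {"solver": "highs", "E_total": esp.E_total},
    )


def enzyme_cost_min(
    net: Network,
    esp: EnzymeSpec,
    fixed: Mapping[str, float] | None = None,
    floor_mu: float | None = None,
) -> FluxSolution:
    """Minimize the weighted enzyme cost sum w_i E_i at fixed demands.

    Demands are fixed fluxes and/or a growth-rate floor; at the optimum
    every enzyme carrying flux is tight, E_i = |r_i| / kcat_i.
    """
    q = len(net.reactions)
    A_eq, var_bounds, A_ub, b_ub, cap_ids, recomb = _capacity_program(
        net, esp, fixed
    )
    if floor_mu is not None:
        from .fba import growth_coefficients

        mu_row = growth_coefficients(net) @ recomb[:, : 2 * q]
        row = np.zeros(2 * q + len(cap_ids))
        row[: 2 * q] = -mu_row
        A_ub = np.vstack([A_ub, row])
        b_ub = np.append(b_ub, -floor_mu)
    cost = np.zeros(2 * q + len(cap_ids))
    for k, rid in enumerate(cap_ids):
        cost[2 * q + k] = esp.weight(rid)
    res = optimize.linprog(
        cost,
        A_eq=A_eq,
        b_eq=np.zeros(A_eq.shape[0]),
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=var_bounds,
        method="highs",
    )
    return _finish(
        net,
        res,
        recomb,
        cap_ids,
        lambda r, E: float(
            sum(esp.weight(rid) * E[k] for k, rid in enumerate(cap_ids))
        ),
        {"solver": "highs", "objective": "min_enzyme"},
    )


def copy_number_to_conc(
    molecules_per_cell: float, cell_mass: float = 1e-12
) -> float:
    """Molecules per cell -> mmol/gDW via Avogadro's number.

    E.g. 2000 molecules in a 1e-12 gDW cell are 3.3e-6 mmol/gDW
    (3.3e-3 umol/gDW).
    """
    if molecules_per_cell < 0 or cell_mass <= 0:
        raise ValueError("molecule count must be >= 0 and cell mass > 0")
    return 1000.0 * molecules_per_cell / (AVOGADRO * cell_mass)


def estimate_kcat(flux: float, enzyme_conc: float) -> float:
    """Apparent turnover number kcat = r / c_E (1/h)."""
    if enzyme_conc <= 0:
        raise ValueError("enzyme concentration must be positive")
    return flux / enzyme_conc
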