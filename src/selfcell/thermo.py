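"""Gibbs-energy bookkeeping and thermodynamic consistency of flux maps.

Four mechanisms keep flux distributions from running around internal
cycles, which no concentration assignment could support:

* the loop-law identity K^T dG = 0 for every cycle-basis vector K,
* a big-M mixed-integer formulation coupling flux signs to dG signs,
* a sign-vector test |s_c^T s_f| < s_c^T s_c per cycle,
* concentration-coupled constraints sign(r) * (dG0'/RT + N'^T x) < 0,

plus the max-min driving force (MDF): the concentration assignment that
maximizes the smallest driving force |dG| along a given flux map.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize

from .fba import _apply_fixed, _balance_rows, _objective_vector, solve_fba
from .model import Network
from .network_core import KernelBasis, internal_cycle_basis
from .solution import INFEASIBLE, OPTIMAL, FluxSolution, Objective

__all__ = [
    "GAS_CONSTANT_KJ",
    "DEFAULT_RT",
    "ThermoSpec",
    "LooplessConfig",
    "CycleConsistencyReport",
    "MdfResult",
    "scaled_delta_g",
    "dg0_from_keq",
    "keq_from_dg0",
    "keq_dg0_interconvert",
    "check_cycle_consistency",
    "sign_loop_test",
    "loopless_fba",
    "tfba_with_concentrations",
    "mdf",
    "sign_pattern",
]

#: gas constant, kJ/mol/K
GAS_CONSTANT_KJ = 8.315e-3

#: RT at T = 300 K (kJ/mol); standard-condition tables use T = 298 K
DEFAULT_RT = GAS_CONSTANT_KJ * 300.0

#: default log-concentration window, ln of [1e-6, 0.1] mmol/gDW
DEFAULT_X_MIN = math.log(1e-6)
DEFAULT_X_MAX = math.log(0.1)


@dataclass
class ThermoSpec:
    """Standard reaction energies and concentration windows.

    ``dg0_prime`` maps internal reaction ids to dG0' (kJ/mol); ``RT`` is
    R*T in kJ/mol; ``x_min``/``x_max`` override the per-compound default
    log-concentration bounds.
    """

    dg0_prime: dict[str, float] = field(default_factory=dict)
    RT: float = DEFAULT_RT
    x_min: dict[str, float] = field(default_factory=dict)
    x_max: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.RT <= 0:
            raise ValueError("RT must be positive")

    @classmethod
    def from_network(cls, net: Network, RT: float = DEFAULT_RT) -> "ThermoSpec":
        """Collect dG0' annotations from the reactions."""
        dg0 = {
            r.id: r.dg0_prime
            for r in net.internal_reactions
            if r.dg0_prime is not None
        }
        return cls(dg0_prime=dg0, RT=RT)

    def dg0_vector(self, net: Network) -> np.ndarray:
        out = []
        for r in net.internal_reactions:
            if r.id in self.dg0_prime:
                out.append(self.dg0_prime[r.id])
            elif r.dg0_prime is not None:
                out.append(r.dg0_prime)
            else:
                raise KeyError(f"no dG0' for internal reaction {r.id!r}")
        return np.array(out)

    def x_bounds(self, net: Network) -> tuple[np.ndarray, np.ndarray]:
        lo = np.empty(len(net.compounds))
        hi = np.empty(len(net.compounds))
        for i, c in enumerate(net.compounds):
            if c.id in self.x_min:
                lo[i] = self.x_min[c.id]
            elif c.conc_min is not None:
                lo[i] = math.log(c.conc_min)
            else:
                lo[i] = DEFAULT_X_MIN
            if c.id in self.x_max:
                hi[i] = self.x_max[c.id]
            elif c.conc_max is not None:
                hi[i] = math.log(c.conc_max)
            else:
                hi[i] = DEFAULT_X_MAX
        return lo, hi


@dataclass
class LooplessConfig:
    """Big-M and strict-inequality margin for the MILP formulation."""

    big_M: float = 1e4
    epsilon: float = 0.1

    def __post_init__(self) -> None:
        if not self.big_M > self.epsilon > 0:
            raise ValueError("need big_M > epsilon > 0")


def scaled_delta_g(
    spec: ThermoSpec, net: Network, x: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """dG = dG0' + RT * N'^T x for the internal reactions.

    ``x`` is the log-concentration vector over all compounds; returns
    (dG in kJ/mol, dG/RT).
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (len(net.compounds),):
        raise ValueError(
            f"x has shape {x.shape}, expected ({len(net.compounds)},)"
        )
    dg0 = spec.dg0_vector(net)
    dg = dg0 + spec.RT * (net.internal_matrix().T @ x)
    return dg, dg / spec.RT


def dg0_from_keq(keq: float, RT: float = DEFAULT_RT) -> float:
    """dG0' = -RT ln K_eq; negative for K_eq > 1."""
    if keq <= 0:
        raise ValueError("K_eq must be positive")
    return -RT * math.log(keq)


def keq_from_dg0(dg0: float, RT: float = DEFAULT_RT) -> float:
    """K_eq = exp(-dG0'/RT)."""
    return math.exp(-dg0 / RT)


def keq_dg0_interconvert(
    value: float, RT: float = DEFAULT_RT, direction: str = "keq_to_dg0"
) -> float:
    """Convert K_eq <-> dG0' (round trip is the identity)."""
    if direction == "keq_to_dg0":
        return dg0_from_keq(value, RT)
    if direction == "dg0_to_keq":
        return keq_from_dg0(value, RT)
    raise ValueError("direction must be 'keq_to_dg0' or 'dg0_to_keq'")


@dataclass
class CycleConsistencyReport:
    """K^T dG0' per basis cycle; zero for a thermodynamically consistent
    parameterization (equivalently the K_eq along each cycle multiply to 1)."""

    residuals: np.ndarray
    tolerance: float

    @property
    def consistent(self) -> bool:
        return bool(np.all(np.abs(self.residuals) <= self.tolerance))


def check_cycle_consistency(
    spec: ThermoSpec,
    cycles: KernelBasis,
    net: Network,
    tolerance: float = 1e-6,
) -> CycleConsistencyReport:
    dg0 = spec.dg0_vector(net)
    residuals = cycles.K.T @ dg0
    return CycleConsistencyReport(
        residuals=np.atleast_1d(residuals), tolerance=tolerance
    )


def sign_loop_test(
    cycle_sign: Sequence[int], flux_sign: Sequence[int]
) -> tuple[int, int, bool]:
    """(|s_c^T s_f|, s_c^T s_c, passes).

    The test passes (lhs < rhs) iff the flux pattern does not run around
    the cycle; equality means the flux follows the cycle.
    """
    sc = np.asarray(cycle_sign, dtype=int)
    sf = np.asarray(flux_sign, dtype=int)
    if sc.shape != sf.shape:
        raise ValueError(f"length mismatch: {sc.shape} vs {sf.shape}")
    for v in np.concatenate([sc, sf]):
        if v not in (-1, 0, 1):
            raise ValueError("sign vectors must contain only -1, 0, +1")
    lhs = int(abs(sc @ sf))
    rhs = int(sc @ sc)
    return lhs, rhs, lhs < rhs


def sign_pattern(
    net: Network, r: np.ndarray, tol: float = 1e-6
) -> dict[str, int]:
    """Sign of each internal flux in a solution vector."""
    r = np.asarray(r, dtype=float)
    out = {}
    for rxn in net.internal_reactions:
        v = r[net.reaction_index(rxn.id)]
        out[rxn.id] = 0 if abs(v) <= tol else (1 if v > 0 else -1)
    return out


# ---------------------------------------------------------------------------
# Loopless FBA (MILP)
# ---------------------------------------------------------------------------


def loopless_fba(
    net: Network,
    obj: Objective,
    spec: ThermoSpec | None = None,
    cfg: LooplessConfig | None = None,
    fixed: Mapping[str, float] | None = None,
) -> FluxSolution:
    """FBA with the big-M loop-law MILP.

    Variables (r, z, dG) with binaries z per internal reaction: z_i = 1
    forces r_i >= 0 and dG_i in [-M, -eps], z_i = 0 forces r_i <= 0 and
    dG_i in [eps, M]; K^T dG = 0 eliminates net flux around every basis
    cycle.  For cycle-free networks the constraints are vacuous and the
    result coincides with plain FBA.
    """
    cfg = cfg or LooplessConfig()
    M, eps = cfg.big_M, cfg.epsilon
    internal = net.internal_reaction_ids
    m = len(internal)
    q = len(net.reactions)
    basis = internal_cycle_basis(net)
    if basis.dimension == 0:
        sol = solve_fba(net, obj, fixed=fixed)
        sol.meta["loopless"] = "no cycles"
        return sol

    c = _objective_vector(net, obj)
    sign = -1.0 if obj.sense == "max" else 1.0
    nvar = q + 2 * m
    cost = np.zeros(nvar)
    cost[:q] = sign * c

    rows_eq = []
    A_bal = _balance_rows(net)
    eq1 = np.zeros((A_bal.shape[0], nvar))
    eq1[:, :q] = A_bal
    rows_eq.append(eq1)
    eq2 = np.zeros((basis.dimension, nvar))
    eq2[:, q + m:] = basis.K.T
    rows_eq.append(eq2)
    A_eq = np.vstack(rows_eq)

    rows_ub = []
    b_ub = []
    for i, rid in enumerate(internal):
        j = net.reaction_index(rid)
        row = np.zeros(nvar)  # r_j - M z_i <= 0
        row[j] = 1.0
        row[q + i] = -M
        rows_ub.append(row)
        b_ub.append(0.0)
        row = np.zeros(nvar)  # -r_j + M z_i <= M   (r_j >= -M(1-z))
        row[j] = -1.0
        row[q + i] = M
        rows_ub.append(row)
        b_ub.append(M)
        row = np.zeros(nvar)  # g_i + (M+eps) z_i <= M
        row[q + m + i] = 1.0
        row[q + i] = M + eps
        rows_ub.append(row)
        b_ub.append(M)
        row = np.zeros(nvar)  # -g_i - (M+eps) z_i <= -eps
        row[q + m + i] = -1.0
        row[q + i] = -(M + eps)
        rows_ub.append(row)
        b_ub.append(-eps)
    A_ub = np.vstack(rows_ub)

    bounds = _apply_fixed(net, fixed)
    lo = np.concatenate(
        [
            [b[0] for b in bounds],
            np.zeros(m),
            np.full(m, -M),
        ]
    )
    hi = np.concatenate(
        [
            [b[1] for b in bounds],
            np.ones(m),
            np.full(m, M),
        ]
    )
    integrality = np.concatenate(
        [np.zeros(q), np.ones(m), np.zeros(m)]
    )
    res = optimize.milp(
        cost,
        constraints=[
            optimize.LinearConstraint(A_eq, 0.0, 0.0),
            optimize.LinearConstraint(A_ub, -np.inf, np.array(b_ub)),
        ],
        bounds=optimize.Bounds(lo, hi),
        integrality=integrality,
    )
    if res.status != 0 or res.x is None:
        return FluxSolution(
            reaction_ids=net.reaction_ids,
            r=None,
            objective_value=None,
            status=INFEASIBLE,
            meta={"solver": "highs-milp", "milp_status": int(res.status)},
        )
    x = np.asarray(res.x)
    r = x[:q]
    z = np.round(x[q : q + m])
    g = x[q + m :]
    flux_at_M = [
        internal[i]
        for i in range(m)
        if abs(g[i]) > M - 1e-6
        and abs(r[net.reaction_index(internal[i])]) > 1e-6
    ]
    if flux_at_M:
        warnings.warn(
            f"|dG| reached big_M on flux-carrying reactions {flux_at_M}; "
            "consider increasing big_M"
        )
    return FluxSolution(
        reaction_ids=net.reaction_ids,
        r=r,
        objective_value=float(c @ r),
        status=OPTIMAL,
        dg=g,
        z=z,
        meta={
            "solver": "highs-milp",
            "internal_ids": internal,
            "epsilon": eps,
            "big_M": M,
        },
    )


# ---------------------------------------------------------------------------
# Concentration-coupled constraints and MDF
# ---------------------------------------------------------------------------


def _direction_bounds(
    net: Network,
    signs: Mapping[str, int],
    fixed: Mapping[str, float] | None,
) -> list[tuple[float, float]]:
    bounds = _apply_fixed(net, fixed)
    for rid, s in signs.items():
        j = net.reaction_index(rid)
        lo, hi = bounds[j]
        if s > 0:
            bounds[j] = (max(lo, 0.0), hi)
        elif s < 0:
            bounds[j] = (lo, min(hi, 0.0))
        else:
            bounds[j] = (0.0, 0.0)
    return bounds


def _x_system(
    net: Network,
    spec: ThermoSpec,
    signs: Mapping[str, int],
    epsilon: float,
    with_B: bool,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Inequalities sign_i * dG_i <= -eps (or <= -B) over x (and B)."""
    l = len(net.compounds)
    Np = net.internal_matrix()
    dg0 = spec.dg0_vector(net)
    rows = []
    rhs = []
    for i, rid in enumerate(net.internal_reaction_ids):
        s = signs.get(rid, 0)
        if s == 0:
            continue
        row = np.zeros(l + (1 if with_B else 0))
        row[:l] = s * spec.RT * Np[:, i]
        if with_B:
            row[l] = 1.0  # ... + B <= -s*dg0
        rows.append(row)
        rhs.append(-s * dg0[i] - (0.0 if with_B else epsilon))
    if not rows:
        raise ValueError("sign pattern has no active internal reactions")
    lo, hi = spec.x_bounds(net)
    return np.vstack(rows), np.array(rhs), lo, hi


def tfba_with_concentrations(
    net: Network,
    obj: Objective,
    spec: ThermoSpec,
    signs: Mapping[str, int],
    epsilon: float = 0.1,
    fixed: Mapping[str, float] | None = None,
) -> FluxSolution:
    """Flux optimization with concentration-backed directions.

    The flux LP is solved with the direction constraints implied by the
    supplied sign pattern; then a log-concentration vector x is sought with
    sign(r_i) * (dG0'_i + RT (N'^T x)_i) <= -epsilon for every running
    internal reaction.  In-cycle sign patterns admit no such x and are
    reported infeasible, with the violated cycle identified.
    """
    reference = solve_fba(net, obj, fixed=fixed)  # direction-free value
    dir_bounds = _direction_bounds(net, signs, fixed)
    c = _objective_vector(net, obj)
    sign = -1.0 if obj.sense == "max" else 1.0
    A_bal = _balance_rows(net)
    res = optimize.linprog(
        sign * c,
        A_eq=A_bal,
        b_eq=np.zeros(A_bal.shape[0]),
        bounds=dir_bounds,
        method="highs",
    )
    if res.status != 0:
        return FluxSolution(
            reaction_ids=net.reaction_ids,
            r=None,
            objective_value=None,
            status=INFEASIBLE,
            meta={"stage": "flux", "solver": "highs"},
        )
    r = np.asarray(res.x)

    A, b, lo, hi = _x_system(net, spec, signs, epsilon, with_B=False)
    xres = optimize.linprog(
        np.zeros(len(lo)),
        A_ub=A,
        b_ub=b,
        bounds=list(zip(lo, hi)),
        method="highs",
    )
    if xres.status != 0:
        meta = {"stage": "concentrations", "solver": "highs"}
        basis = internal_cycle_basis(net)
        sf = [signs.get(rid, 0) for rid in net.internal_reaction_ids]
        for k in range(basis.dimension):
            sc = np.sign(np.round(basis.K[:, k], 12)).astype(int)
            lhs, rhs_v, passes = sign_loop_test(sc, sf)
            if not passes:
                meta["violated_cycle"] = {
                    "reactions": [
                        rid
                        for rid, s in zip(net.internal_reaction_ids, sc)
                        if s != 0
                    ],
                    "lhs": lhs,
                    "rhs": rhs_v,
                }
        return FluxSolution(
            reaction_ids=net.reaction_ids,
            r=None,
            objective_value=None,
            status=INFEASIBLE,
            meta=meta,
        )
    x = np.asarray(xres.x)
    dg, _ = scaled_delta_g(spec, net, x)
    return FluxSolution(
        reaction_ids=net.reaction_ids,
        r=r,
        objective_value=float(c @ r),
        status=OPTIMAL,
        x=x,
        dg=dg,
        meta={
            "solver": "highs",
            "epsilon": epsilon,
            "internal_ids": net.internal_reaction_ids,
            "reference_objective": reference.objective_value,
        },
    )


@dataclass
class MdfResult:
    """Max-min driving force: the optimal margin B (kJ/mol), a witness
    log-concentration vector and the resulting reaction energies."""

    B: float
    x: np.ndarray | None
    dg: np.ndarray | None
    status: str

    @property
    def ok(self) -> bool:
        return self.status == OPTIMAL


def mdf(
    net: Network,
    spec: ThermoSpec,
    signs: Mapping[str, int],
) -> MdfResult:
    """Maximize the smallest driving force along a given flux map.

    LP over (x, B): max B subject to -sign(r_i) dG_i >= B for every
    running internal reaction and the log-concentration bounds.
    """
    A, b, lo, hi = _x_system(net, spec, signs, 0.0, with_B=True)
    l = len(lo)
    cost = np.zeros(l + 1)
    cost[l] = -1.0  # maximize B
    res = optimize.linprog(
        cost,
        A_ub=A,
        b_ub=b,
        bounds=list(zip(lo, hi)) + [(None, None)],
        method="highs",
    )
    if res.status != 0:
        return MdfResult(B=math.nan, x=None, dg=None, status=INFEASIBLE)
    x = np.asarray(res.x[:l])
    B = float(res.x[l])
    dg, _ = scaled_delta_g(spec, net, x)
    return MdfResult(B=B, x=x, dg=dg, status=OPTIMAL)
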