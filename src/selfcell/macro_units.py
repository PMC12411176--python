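"""Biomass handling: pseudo-reactions, the M-matrix growth law and
coarse-grained macromolecular units.

Standard FBA drains precursors through a single biomass pseudo-reaction
whose molar coefficients are mass fractions divided by molecular weights.
The mass-conservative alternative keeps the macromolecular units (protein-
like B1, ribosome-like B2, inert B3, ...) as first-class compounds: the
growth rate becomes mu = w^T N r / 1000 and the steady state of every
concentration c includes the dilution term mu*c, compactly
(I - c w^T) N r = M N r = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize

from .model import Reaction

__all__ = [
    "BiomassComposition",
    "UnitSpec",
    "UnitModel",
    "MMatrix",
    "biomass_pseudoreaction",
    "molar_coefficients",
    "build_m_matrix",
    "unit_steady_state",
    "reduced_allocation_scan",
    "optimal_allocation",
    "scenario_sweep",
]


@dataclass
class BiomassComposition:
    """Mass fractions (g/g) of the biomass precursors; they sum to 1."""

    fractions: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mass fractions sum to {total}, expected 1")
        for cid, f in self.fractions.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"fraction of {cid!r} outside [0, 1]")


@dataclass
class UnitSpec:
    """One macromolecular unit.

    ``mass_fraction`` B_j in g/g; ``monomer_stoich`` maps monomer compound
    id to mol monomer per mol unit (large values: many monomers per unit).
    ``gating``: "none" for units whose synthesis rate simply follows
    mu*B_j, "self" for a unit whose synthesis is autocatalytic and coupled
    to a gating metabolite through f_M = M/K_M (rate k_syn * f_M * B_j).
    """

    id: str
    mass_fraction: float
    monomer_stoich: dict[str, float] = field(default_factory=dict)
    gating: str = "none"
    k_syn: float | None = None
    k_m: float | None = None
    gating_metabolite: str | None = None

    def __post_init__(self) -> None:
        for cid, g in self.monomer_stoich.items():
            if g <= 0:
                raise ValueError(
                    f"unit {self.id!r}: monomer stoichiometry for {cid!r} "
                    "must be positive"
                )
        if self.gating not in ("none", "self", "metabolite"):
            raise ValueError(f"unit {self.id!r}: unknown gating {self.gating!r}")

    def molecular_weight(self, monomer_weights: Mapping[str, float]) -> float:
        """gamma_j * w_monomer summed over the monomer mix (g/mol)."""
        return sum(
            g * monomer_weights[cid] for cid, g in self.monomer_stoich.items()
        )


@dataclass
class UnitModel:
    """A set of macromolecular units layered on a network.

    Mass closure: sum of unit fractions plus the metabolite budget (plus
    enzyme mass, handled by the self-contained layer) equals 1 g/g.
    """

    units: list[UnitSpec]
    metabolite_mass_budget: float = 0.1

    def __post_init__(self) -> None:
        ids = [u.id for u in self.units]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate unit ids")

    def unit(self, uid: str) -> UnitSpec:
        for u in self.units:
            if u.id == uid:
                return u
        raise KeyError(uid)

    @property
    def total_unit_fraction(self) -> float:
        return sum(u.mass_fraction for u in self.units)


@dataclass
class MMatrix:
    """M = I - c w^T / 1000 with c in mmol/gDW and w in g/mol.

    For any flux vector r: M N r = N r - (w^T N r / 1000) c = N r - mu c,
    i.e. the right side of the concentration balance at steady state.
    """

    matrix: np.ndarray
    c: np.ndarray
    w: np.ndarray


def molar_coefficients(
    fractions: Mapping[str, float], weights: Mapping[str, float]
) -> dict[str, float]:
    """fraction / weight per compound, in mol/gDW (the printed convention
    for biomass equations, e.g. 0.35 g of a 150 g/mol compound ->
    2.33e-3 mol/gDW)."""
    missing = [cid for cid in fractions if cid not in weights]
    if missing:
        raise KeyError(f"no molecular weight for {missing}")
    return {cid: f / weights[cid] for cid, f in fractions.items()}


def biomass_pseudoreaction(
    fractions: Mapping[str, float],
    weights: Mapping[str, float],
    rid: str = "biomass",
) -> Reaction:
    """Drain reaction whose flux variable is the growth rate mu (1/h).

    Stoichiometric coefficients are stored on the package-wide mmol basis
    (1000 * fraction / weight, mmol/gDW) so that coefficient x mu has flux
    units; the drained mass per unit mu is exactly 1 g/gDW.  No product
    species: biomass is not a row of N.
    """
    BiomassComposition(dict(fractions))  # validates closure
    molar = molar_coefficients(fractions, weights)
    return Reaction(
        id=rid,
        stoich={cid: -1000.0 * coef for cid, coef in molar.items()},
        lower_bound=0.0,
        is_internal=False,
        allows_mass_loss=True,
    )


def build_m_matrix(c: np.ndarray, w: np.ndarray) -> MMatrix:
    """Outer-product form M = I - c w^T / 1000 (dimensionless g/g terms)."""
    c = np.asarray(c, dtype=float)
    w = np.asarray(w, dtype=float)
    if c.shape != w.shape or c.ndim != 1:
        raise ValueError(
            f"c and w must be equal-length vectors, got {c.shape} and {w.shape}"
        )
    matrix = np.eye(len(c)) - np.outer(c, w) / 1000.0
    return MMatrix(matrix=matrix, c=c, w=w)


def unit_steady_state(
    model: UnitModel,
    mu: float,
    monomer_weights: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Synthesis rates balancing growth dilution: r_syn,j = mu * B_j.

    Returns per unit the mass synthesis rate (g/gDW/h) and, when monomer
    weights are available, the molar rate (mmol/gDW/h) obtained through
    the unit molecular weight gamma_j * w_monomer.
    """
    if mu < 0:
        raise ValueError("mu must be non-negative")
    rows = []
    for u in model.units:
        mass_rate = mu * u.mass_fraction
        molar_rate = np.nan
        if monomer_weights is not None and u.monomer_stoich:
            molar_rate = 1000.0 * mass_rate / u.molecular_weight(monomer_weights)
        rows.append(
            {
                "unit": u.id,
                "mass_fraction": u.mass_fraction,
                "mass_rate": mass_rate,
                "molar_rate": molar_rate,
            }
        )
    return pd.DataFrame(rows).set_index("unit")


# ---------------------------------------------------------------------------
# Reduced two-unit allocation model
# ---------------------------------------------------------------------------
#
# Metabolite A (negligible mass fraction) feeds one structured biomass flux.
# Unit B1 gates the uptake (r0 = k1*B1), unit B2 gates biomass synthesis
# (r2 = k2*B2); all three rates are mass fluxes in g/gDW/h, so with the
# total biomass scaled to B_total the growth rate is mu = r2 and the
# overflow closes the A balance: r1 = r0 - r2.  Steady states with r1 < 0
# would require taking the overflow product back up and are marked
# infeasible; the optimum sits where uptake and synthesis exactly match,
# B1* = k2 B / (k1 + k2), giving mu* = k1 k2 B / (k1 + k2) — hyperbolic in
# k1 and linear in the available biomass B.


def reduced_allocation_scan(
    model: UnitModel | None,
    k1: float,
    k2: float,
    B_total: float = 1.0,
    grid: int = 401,
) -> tuple[pd.DataFrame, dict]:
    """Scan B1 over [0, B_total] and report (B1, r0, r1, r2, mu).

    Returns the full solution space (including the infeasible r1 < 0
    branch, flagged) and the feasible optimum.
    """
    if k1 <= 0 or k2 <= 0:
        raise ValueError("k1 and k2 must be positive")
    if grid < 3:
        raise ValueError("grid must have at least 3 points")
    b1 = np.linspace(0.0, B_total, grid)
    b2 = B_total - b1
    r0 = k1 * b1
    r2 = k2 * b2
    r1 = r0 - r2
    mu = r2.copy()
    feasible = r1 >= -1e-12
    table = pd.DataFrame(
        {"B1": b1, "B2": b2, "r0": r0, "r1": r1, "r2": r2, "mu": mu,
         "feasible": feasible}
    )
    if feasible.any():
        idx = int(np.flatnonzero(feasible)[np.argmax(mu[feasible])])
        optimum = {
            "B1": float(b1[idx]),
            "B2": float(b2[idx]),
            "mu": float(mu[idx]),
            "r0": float(r0[idx]),
            "r1": float(r1[idx]),
            "r2": float(r2[idx]),
        }
    else:  # pragma: no cover - cannot happen for positive k
        optimum = {}
    return table, optimum


def optimal_allocation(k1: float, k2: float, B_total: float = 1.0) -> dict:
    """Continuous optimum of the reduced model (no grid).

    Solved numerically as the 1-D maximization of min(k1*B1, k2*(B-B1)),
    the realizable growth rate at allocation B1.
    """
    res = optimize.minimize_scalar(
        lambda b1: -min(k1 * b1, k2 * (B_total - b1)),
        bounds=(0.0, B_total),
        method="bounded",
        options={"xatol": 1e-12},
    )
    b1 = float(res.x)
    return {"B1": b1, "B2": B_total - b1, "mu": float(-res.fun)}


def scenario_sweep(
    model: UnitModel | None,
    scenario: str,
    values: list[float],
    k1: float = 3.0,
    k2: float = 1.5,
    B_total: float = 1.0,
) -> pd.DataFrame:
    """Re-optimize the reduced allocation under perturbed conditions.

    ``substrate_limitation`` rescales the uptake gain k1 by each value
    (value acting as a substrate-availability factor); ``heterologous_burden``
    removes the value from the allocatable biomass (a burden b makes only
    B_total - b available).
    """
    rows = []
    if scenario == "substrate_limitation":
        for v in values:
            opt = optimal_allocation(k1 * v, k2, B_total)
            rows.append({"value": v, **opt})
    elif scenario == "heterologous_burden":
        for v in values:
            avail = B_total - v
            if avail <= 0:
                rows.append(
                    {"value": v, "B1": 0.0, "B2": 0.0, "mu": 0.0}
                )
                continue
            opt = optimal_allocation(k1, k2, avail)
            rows.append({"value": v, **opt})
    else:
        raise ValueError(
            f"unknown scenario {scenario!r}; choose 'substrate_limitation' "
            "or 'heterologous_burden'"
        )
    return pd.DataFrame(rows)
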