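"""Flux solutions and linear objectives."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["FluxSolution", "Objective", "OPTIMAL", "INFEASIBLE", "UNBOUNDED"]

OPTIMAL = "optimal"
INFEASIBLE = "infeasible"
UNBOUNDED = "unbounded"


@dataclass
class FluxSolution:
    """Result of one flux computation.

    ``r`` is the flux vector (mmol/gDW/h) aligned with ``reaction_ids``.
    Optional payloads: growth rate ``mu`` (1/h), log-concentrations ``x``,
    reaction energies ``dg`` (kJ/mol), loopless binaries ``z``, enzyme
    levels ``enzymes`` (mmol/gDW).  ``meta`` carries the run manifest
    (solver, tolerances, degeneracy flags, multistart log, ...).
    """

    reaction_ids: list[str]
    r: np.ndarray | None
    objective_value: float | None
    status: str
    mu: float | None = None
    x: np.ndarray | None = None
    dg: np.ndarray | None = None
    z: np.ndarray | None = None
    enzymes: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def fluxes(self) -> pd.Series:
        if self.r is None:
            return pd.Series(dtype=float)
        return pd.Series(self.r, index=self.reaction_ids, name="flux")

    def __getitem__(self, rid: str) -> float:
        if self.r is None:
            raise KeyError(f"no flux vector (status={self.status})")
        return float(self.r[self.reaction_ids.index(rid)])

    @property
    def ok(self) -> bool:
        return self.status == OPTIMAL

    def support(self, tol: float = 1e-6) -> set[str]:
        """Reaction ids with |flux| > tol."""
        if self.r is None:
            return set()
        return {
            rid for rid, v in zip(self.reaction_ids, self.r) if abs(v) > tol
        }


@dataclass
class Objective:
    """A linear objective over reaction fluxes.

    ``kind`` is a label ("linear", "total_flux", "growth", "min_enzyme",
    "max_min_driving_force"); the solvers dispatch on it where the objective
    is not a plain linear form.  ``coefficients`` maps reaction id -> g_i.
    """

    kind: str = "linear"
    coefficients: Mapping[str, float] = field(default_factory=dict)
    sense: str = "max"

    def __post_init__(self) -> None:
        if self.sense not in ("max", "min"):
            raise ValueError("sense must be 'max' or 'min'")

    # -- constructors --------------------------------------------------

    @classmethod
    def maximize(cls, rid: str) -> "Objective":
        return cls(kind="linear", coefficients={rid: 1.0}, sense="max")

    @classmethod
    def minimize(cls, rid: str) -> "Objective":
        return cls(kind="linear", coefficients={rid: 1.0}, sense="min")

    @classmethod
    def total_flux(cls) -> "Objective":
        return cls(kind="total_flux", coefficients={}, sense="min")

    @classmethod
    def growth(cls) -> "Objective":
        """Maximize mu = w^T N r / 1000.

        On a fully balanced network w^T N r vanishes identically, so the
        accounting runs over the rows exempt from balancing: external
        biomass/unit compounds plus biomass-style drain pseudo-reactions
        (whose flux equals mu by construction).
        """
        return cls(kind="growth", coefficients={}, sense="max")

    def vector(self, reaction_ids: list[str]) -> np.ndarray:
        missing = set(self.coefficients) - set(reaction_ids)
        if missing:
            raise KeyError(
                f"objective references unknown reactions: {sorted(missing)}"
            )
        return np.array(
            [self.coefficients.get(rid, 0.0) for rid in reaction_ids]
        )
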