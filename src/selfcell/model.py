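"""Core containers: compounds, reactions and the stoichiometric network.

Conventions used throughout the package (documented once, here):

* fluxes            mmol/gDW/h
* concentrations    mmol/gDW
* molecular weights g/mol
* reaction energies kJ/mol
* growth rate       1/h

With these units the specific growth rate is ``mu = w @ N @ r / 1000``:
(g/mol) * (mmol/gDW/h) = mg/gDW/h, and the factor 1000 converts to
g/gDW/h = 1/h.  The factor is applied inside the growth-rate helpers, never
by callers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "Compound",
    "Reaction",
    "Network",
    "ModelValidationError",
    "MASS_TOLERANCE",
    "DEFAULT_REVERSIBLE_BOUND",
    "DEFAULT_IRREVERSIBLE_BOUND",
]

#: g/mol residual below which a reaction counts as mass conserving
MASS_TOLERANCE = 1e-6

#: default flux bounds (mmol/gDW/h) where a model file gives none
DEFAULT_REVERSIBLE_BOUND = 1000.0
DEFAULT_IRREVERSIBLE_BOUND = 1000.0


class ModelValidationError(ValueError):
    """A network or one of its parts violates a structural invariant."""


@dataclass
class Compound:
    """A chemical species carried by the cell (or an external pool).

    molecular_weight is optional for pure-flux use; conc_min/conc_max bound
    the concentration (mmol/gDW) for thermodynamic calculations;
    mass_fraction (g/g) is used when the compound is part of a biomass
    composition.
    """

    id: str
    molecular_weight: float | None = None
    is_external: bool = False
    conc_min: float | None = None
    conc_max: float | None = None
    mass_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.molecular_weight is not None and self.molecular_weight <= 0:
            raise ModelValidationError(
                f"compound {self.id!r}: molecular_weight must be positive"
            )
        if (
            self.conc_min is not None
            and self.conc_max is not None
            and self.conc_min > self.conc_max
        ):
            raise ModelValidationError(
                f"compound {self.id!r}: conc_min > conc_max"
            )


@dataclass
class Reaction:
    """A stoichiometric reaction column.

    ``stoich`` maps compound id to the signed molar coefficient (substrates
    negative).  ``allows_mass_loss`` marks reactions whose imbalance is an
    implicit excreted by-product rather than a modelling error.  Optional
    thermodynamic (``dg0_prime``, kJ/mol) and enzymatic (``kcat``, 1/h;
    ``kinetic_law``) annotations hang off the reaction.
    """

    id: str
    stoich: dict[str, float]
    lower_bound: float = -DEFAULT_REVERSIBLE_BOUND
    upper_bound: float = DEFAULT_REVERSIBLE_BOUND
    is_internal: bool = True
    dg0_prime: float | None = None
    kcat: float | None = None
    kinetic_law: object | None = None
    allows_mass_loss: bool = False

    def __post_init__(self) -> None:
        if not self.stoich:
            raise ModelValidationError(f"reaction {self.id!r}: empty stoichiometry")
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id!r}: lower_bound > upper_bound"
            )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    def mass_residual(self, weights: Mapping[str, float]) -> float:
        """w^T n for this column, in g/mol; 0 for a closed balance."""
        try:
            return sum(coef * weights[cid] for cid, coef in self.stoich.items())
        except KeyError as exc:  # pragma: no cover - defensive
            raise ModelValidationError(
                f"reaction {self.id!r}: no molecular weight for compound {exc.args[0]!r}"
            ) from None


@dataclass
class Network:
    """An ordered collection of compounds and reactions.

    The dense stoichiometric matrix ``N`` has one row per compound and one
    column per reaction (l x q).  External pools are normally not listed as
    compounds; exchange reactions simply have net stoichiometry on the
    internal species and ``is_internal=False``.
    """

    compounds: list[Compound] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    # -- bookkeeping ---------------------------------------------------

    def validate(self) -> None:
        ids = [c.id for c in self.compounds]
        if len(set(ids)) != len(ids):
            raise ModelValidationError("duplicate compound ids")
        rids = [r.id for r in self.reactions]
        if len(set(rids)) != len(rids):
            raise ModelValidationError("duplicate reaction ids")
        known = set(ids)
        for rxn in self.reactions:
            for cid in rxn.stoich:
                if cid not in known:
                    raise ModelValidationError(
                        f"reaction {rxn.id!r} references unknown compound {cid!r}"
                    )

    @property
    def compound_ids(self) -> list[str]:
        return [c.id for c in self.compounds]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def compound(self, cid: str) -> Compound:
        for c in self.compounds:
            if c.id == cid:
                return c
        raise KeyError(cid)

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def compound_index(self, cid: str) -> int:
        return self.compound_ids.index(cid)

    def reaction_index(self, rid: str) -> int:
        return self.reaction_ids.index(rid)

    # -- matrices ------------------------------------------------------

    @property
    def stoichiometric_matrix(self) -> np.ndarray:
        """Dense N, shape (l compounds, q reactions)."""
        N = np.zeros((len(self.compounds), len(self.reactions)))
        cindex = {c.id: i for i, c in enumerate(self.compounds)}
        for j, rxn in enumerate(self.reactions):
            for cid, coef in rxn.stoich.items():
                N[cindex[cid], j] = coef
        return N

    #: short alias used throughout the literature
    @property
    def N(self) -> np.ndarray:
        return self.stoichiometric_matrix

    @property
    def internal_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions if r.is_internal]

    @property
    def internal_reaction_ids(self) -> list[str]:
        return [r.id for r in self.internal_reactions]

    def internal_matrix(self) -> np.ndarray:
        """N' — the columns of the internal reactions (all compound rows)."""
        N = self.stoichiometric_matrix
        cols = [j for j, r in enumerate(self.reactions) if r.is_internal]
        return N[:, cols]

    def weights(self, strict: bool = True) -> np.ndarray:
        """Vector of molecular weights (g/mol) in compound order."""
        out = np.empty(len(self.compounds))
        for i, c in enumerate(self.compounds):
            if c.molecular_weight is None:
                if strict:
                    raise ModelValidationError(
                        f"compound {c.id!r} has no molecular weight"
                    )
                out[i] = np.nan
            else:
                out[i] = c.molecular_weight
        return out

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower_bound for r in self.reactions])
        ub = np.array([r.upper_bound for r in self.reactions])
        return lb, ub

    # -- editing helpers ----------------------------------------------

    def add_compound(self, compound: Compound) -> None:
        if compound.id in self.compound_ids:
            raise ModelValidationError(f"duplicate compound id {compound.id!r}")
        self.compounds.append(compound)

    def add_reaction(self, reaction: Reaction) -> None:
        if reaction.id in self.reaction_ids:
            raise ModelValidationError(f"duplicate reaction id {reaction.id!r}")
        known = set(self.compound_ids)
        for cid in reaction.stoich:
            if cid not in known:
                raise ModelValidationError(
                    f"reaction {reaction.id!r} references unknown compound {cid!r}"
                )
        self.reactions.append(reaction)

    def copy(self) -> "Network":
        import copy as _copy

        return _copy.deepcopy(self)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<Network {len(self.compounds)} compounds x "
            f"{len(self.reactions)} reactions>"
        )


def require_same_length(a: Iterable, b: Iterable, what: str) -> None:
    la, lb = len(list(a)), len(list(b))
    if la != lb:
        raise ValueError(f"{what}: length mismatch ({la} vs {lb})")
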