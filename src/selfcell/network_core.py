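"""Stoichiometric linear algebra.

Mass-conservation auditing (w^T n = 0 per column), numerical rank and
null space, internal cycle bases, the growth rate mu = w^T N r / 1000,
dilution-term assessment, and elementary-flux-mode enumeration for small
networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import MASS_TOLERANCE, ModelValidationError, Network

__all__ = [
    "ConservationReport",
    "KernelBasis",
    "FluxModeSet",
    "audit_mass_conservation",
    "rank_and_nullspace",
    "internal_cycle_basis",
    "growth_rate_from_fluxes",
    "dilution_ratio",
    "enumerate_efms",
    "EFM_SIZE_GUARD",
]

#: exhaustive enumeration guard (columns after reversibility splitting)
EFM_SIZE_GUARD = 20


@dataclass
class ConservationReport:
    """Per-reaction mass residuals w^T n_i (g/mol).

    ``flagged`` lists internal reactions whose residual exceeds the
    tolerance without an ``allows_mass_loss`` annotation.  Exchange
    reactions move mass across the cell boundary, so their residuals are
    reported but never flagged.
    """

    residuals: dict[str, float]
    flagged: list[str]
    tolerance: float = MASS_TOLERANCE

    @property
    def conserved(self) -> bool:
        return not self.flagged


@dataclass
class KernelBasis:
    """Orthonormal null-space basis K (columns) of a matrix."""

    K: np.ndarray
    rank: int
    tolerance: float
    reaction_ids: list[str] | None = None

    @property
    def dimension(self) -> int:
        return self.K.shape[1]


@dataclass
class FluxModeSet:
    """Elementary flux modes of a network.

    Each column of ``modes`` is one mode, normalized to unit uptake flux
    when an exchange uptake is in its support, otherwise to +1 on its
    first nonzero coordinate.
    """

    reaction_ids: list[str]
    modes: list[np.ndarray] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.modes)

    def supports(self, tol: float = 1e-9) -> list[frozenset[str]]:
        out = []
        for m in self.modes:
            out.append(
                frozenset(
                    rid
                    for rid, v in zip(self.reaction_ids, m)
                    if abs(v) > tol
                )
            )
        return out

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            np.array(self.modes), columns=self.reaction_ids
        )
        frame.index.name = "mode"
        return frame


def audit_mass_conservation(
    net: Network, tolerance: float = MASS_TOLERANCE
) -> ConservationReport:
    """Check w^T n = 0 for every reaction column."""
    weights = {c.id: c.molecular_weight for c in net.compounds}
    residuals: dict[str, float] = {}
    flagged: list[str] = []
    for rxn in net.reactions:
        missing = [
            cid for cid in rxn.stoich if weights.get(cid) is None
        ]
        if missing:
            raise ModelValidationError(
                f"reaction {rxn.id!r}: no molecular weight for {missing}"
            )
        res = sum(coef * weights[cid] for cid, coef in rxn.stoich.items())
        residuals[rxn.id] = res
        if (
            rxn.is_internal
            and not rxn.allows_mass_loss
            and abs(res) > tolerance
        ):
            flagged.append(rxn.id)
    return ConservationReport(
        residuals=residuals, flagged=flagged, tolerance=tolerance
    )


def rank_and_nullspace(
    matrix: np.ndarray, tol: float = 1e-9
) -> KernelBasis:
    """Numerical rank and orthonormal kernel via SVD.

    Singular values above ``tol`` times the largest one count toward the
    rank; rank + kernel dimension equals the column count.
    """
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    if matrix.size == 0:
        raise ValueError("empty matrix")
    _, s, vt = np.linalg.svd(matrix)
    cutoff = tol * (s[0] if s.size else 0.0)
    rank = int(np.sum(s > cutoff))
    K = vt[rank:].T  # orthonormal columns spanning the kernel
    return KernelBasis(K=K, rank=rank, tolerance=tol)


def internal_cycle_basis(net: Network, tol: float = 1e-9) -> KernelBasis:
    """Null space of the internal-reaction submatrix N'.

    The kernel vectors are the (basis) cycles of the network: flux
    patterns over internal reactions with no net conversion, which
    thermodynamics forbids from carrying net flux.
    """
    ids = net.internal_reaction_ids
    if not ids:
        raise ModelValidationError("network has no internal reactions")
    basis = rank_and_nullspace(net.internal_matrix(), tol=tol)
    basis.reaction_ids = ids
    return basis


def growth_rate_from_fluxes(net: Network, r: np.ndarray) -> float:
    """mu = w^T N r / 1000 (1/h).

    Fully mass-conserved columns contribute zero; uptake adds mass,
    excretion and by-product losses remove it.  The result may be negative
    for net mass-losing flux maps.
    """
    r = np.asarray(r, dtype=float)
    if r.shape != (len(net.reactions),):
        raise ValueError(
            f"flux vector has length {r.shape}, expected {len(net.reactions)}"
        )
    w = net.weights()
    return float(w @ net.stoichiometric_matrix @ r) / 1000.0


def dilution_ratio(uptake: float, mu: float, conc: float) -> float:
    """uptake / (mu * conc): how much larger a metabolic flux is than the
    growth-dilution term, justifying the steady-state simplification
    N r = 0 when the ratio is large."""
    if uptake <= 0 or mu <= 0 or conc <= 0:
        raise ValueError("uptake, mu and conc must all be positive")
    return uptake / (mu * conc)


# ---------------------------------------------------------------------------
# Elementary flux modes
# ---------------------------------------------------------------------------


def _extreme_rays(A: np.ndarray, tol: float = 1e-10) -> list[np.ndarray]:
    """Extreme rays of {x >= 0 : A x = 0} by the double description method
    with support-minimality filtering after each imposed equality."""
    n = A.shape[1]
    rays: list[np.ndarray] = [np.eye(n)[i] for i in range(n)]
    for a in A:
        vals = [float(a @ r) for r in rays]
        scale = max(1.0, max(abs(v) for v in vals) if vals else 1.0)
        zero = [r for r, v in zip(rays, vals) if abs(v) <= tol * scale]
        pos = [(r, v) for r, v in zip(rays, vals) if v > tol * scale]
        neg = [(r, v) for r, v in zip(rays, vals) if v < -tol * scale]
        new = list(zero)
        for rp, vp in pos:
            for rn, vn in neg:
                comb = vp * rn - vn * rp
                comb = comb / np.max(np.abs(comb))
                new.append(comb)
        # keep only support-minimal rays (Schuster-style tableau filter)
        sups = [frozenset(np.flatnonzero(np.abs(r) > tol)) for r in new]
        keep = []
        seen: set[frozenset] = set()
        for i, (r, s) in enumerate(zip(new, sups)):
            if s in seen:
                continue
            if any(o < s for o in sups):
                continue
            seen.add(s)
            keep.append(r)
        rays = keep
    return rays


def _is_uptake(net: Network, rid: str) -> bool:
    rxn = net.reaction(rid)
    return not rxn.is_internal and sum(rxn.stoich.values()) > 0


def _normalize_mode(net: Network, mode: np.ndarray, tol: float) -> np.ndarray:
    for j, rid in enumerate(net.reaction_ids):
        if abs(mode[j]) > tol and _is_uptake(net, rid) and mode[j] > 0:
            return mode / mode[j]
    nz = np.flatnonzero(np.abs(mode) > tol)
    return mode / mode[nz[0]]


def enumerate_efms(
    net: Network,
    reversibilities: list[bool] | None = None,
    tol: float = 1e-9,
) -> FluxModeSet:
    """All elementary flux modes of a small network.

    A mode is a steady-state flux vector (N r = 0 over all compound rows)
    respecting irreversibility whose support cannot be reduced.  Reversible
    reactions are split into forward/backward parts; the extreme rays of
    the resulting pointed cone are recombined, futile two-cycles dropped,
    and every surviving support verified support-minimal by a rank test.
    """
    q = len(net.reactions)
    if reversibilities is None:
        reversibilities = [r.reversible for r in net.reactions]
    if len(reversibilities) != q:
        raise ValueError("reversibility flags must match the reaction count")
    n_split = q + sum(reversibilities)
    if n_split > EFM_SIZE_GUARD:
        raise ValueError(
            f"network too large for exhaustive enumeration ({n_split} split "
            f"columns > {EFM_SIZE_GUARD}); use a dedicated EFM tool"
        )
    N = net.stoichiometric_matrix
    keep = [i for i, c in enumerate(net.compounds) if not c.is_external]
    N = N[keep, :]  # steady state applies to the balanced rows only
    cols = [N[:, j] for j in range(q)]
    back = [j for j in range(q) if reversibilities[j]]
    A = np.column_stack(cols + [-N[:, j] for j in back])

    modes: list[np.ndarray] = []
    sups: list[frozenset[int]] = []
    for ray in _extreme_rays(A):
        r = ray[:q].copy()
        for k, j in enumerate(back):
            r[j] -= ray[q + k]
        if np.max(np.abs(r)) <= tol:
            continue  # futile forward/backward two-cycle
        support = frozenset(np.flatnonzero(np.abs(r) > tol * np.max(np.abs(r))))
        # elementarity: the support must pin the flux direction up to scale
        sub = N[:, sorted(support)]
        kernel = rank_and_nullspace(sub)
        if kernel.dimension != 1:
            continue
        if support in sups:
            continue
        sups.append(support)
        modes.append(_normalize_mode(net, r, tol))
    # defensive: drop any support that strictly contains another
    keep = [
        i
        for i, s in enumerate(sups)
        if not any(o < s for o in sups)
    ]
    return FluxModeSet(
        reaction_ids=net.reaction_ids, modes=[modes[i] for i in keep]
    )
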