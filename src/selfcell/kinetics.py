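"""Enzymatic rate laws.

Irreversible Michaelis-Menten, and a generalized reversible law for
``n_i S_i -> n_j P_j`` conversions in which the rate factorizes into a
capacity term (kcat*E), a saturation term (0..1) and a thermodynamic term
1 - Q/K_eq, with Q the mass-action ratio.  The Haldane relationship ties
the kinetic constants to K_eq so that the rate vanishes exactly at
chemical equilibrium.

Concentrations use the repository-wide mmol/gDW convention; the binding
constants K_S, K_P, K_M carry those units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

__all__ = [
    "KineticLaw",
    "mm_rate",
    "reversible_rate",
    "rate_decomposition",
    "haldane_keq",
    "enzyme_demand",
    "ThermodynamicallyInfeasible",
]


class ThermodynamicallyInfeasible(ValueError):
    """Requested flux direction conflicts with the mass-action ratio."""


@dataclass
class KineticLaw:
    """Parameters of one reaction's rate law.

    For the reversible law: ``Ks``/``Kp`` map substrate/product compound ids
    to binding constants (mmol/gDW) and ``orders`` to integer
    molecularities (default 1).  ``k_eq`` is the equilibrium constant; when
    None the reaction is treated as irreversible (thermodynamic term = 1).
    ``kcat_minus`` (1/h), when given, must satisfy the Haldane relationship
    K_eq = kcat+ K_P / (kcat- K_S); if ``k_eq`` is absent it is derived
    from it.  ``k_m`` is only used by the plain Michaelis-Menten form.
    """

    kcat: float
    Ks: dict[str, float] = field(default_factory=dict)
    Kp: dict[str, float] = field(default_factory=dict)
    orders: dict[str, int] = field(default_factory=dict)
    k_eq: float | None = None
    kcat_minus: float | None = None
    k_m: float | None = None

    def __post_init__(self) -> None:
        if self.kcat <= 0:
            raise ValueError("kcat must be positive")
        for name, table in (("Ks", self.Ks), ("Kp", self.Kp)):
            for cid, val in table.items():
                if val <= 0:
                    raise ValueError(f"{name}[{cid!r}] must be positive")
        for cid, n in self.orders.items():
            if n != int(n) or n < 1:
                raise ValueError(
                    f"molecularity for {cid!r} must be a positive integer"
                )
            self.orders[cid] = int(n)
        if self.k_eq is not None and self.k_eq <= 0:
            raise ValueError("k_eq must be positive")
        if self.kcat_minus is not None:
            if len(self.Ks) != 1 or len(self.Kp) != 1:
                raise ValueError(
                    "kcat_minus (Haldane form) requires exactly one substrate "
                    "and one product binding constant"
                )
            implied = haldane_keq(
                self.kcat,
                self.kcat_minus,
                next(iter(self.Ks.values())),
                next(iter(self.Kp.values())),
            )
            if self.k_eq is None:
                self.k_eq = implied
            elif abs(self.k_eq - implied) > 1e-9 * implied:
                raise ValueError(
                    "k_eq inconsistent with Haldane relationship: "
                    f"given {self.k_eq}, implied {implied}"
                )

    def order(self, cid: str) -> int:
        return self.orders.get(cid, 1)


def mm_rate(law: KineticLaw, E: float, S: float) -> float:
    """Irreversible Michaelis-Menten rate r = kcat E S / (S + K_M).

    Bounded by the capacity kcat*E; half-saturated at S = K_M.
    """
    if E < 0 or S < 0:
        raise ValueError("E and S must be non-negative")
    km = law.k_m
    if km is None:
        if len(law.Ks) == 1:
            km = next(iter(law.Ks.values()))
        else:
            raise ValueError("law has no Michaelis constant")
    return law.kcat * E * S / (S + km)


def _mass_action_ratio(
    law: KineticLaw, S: Mapping[str, float], P: Mapping[str, float]
) -> float:
    """Q = prod P^n / prod S^n (inf when a substrate is exhausted)."""
    num = 1.0
    for cid in law.Kp:
        num *= P.get(cid, 0.0) ** law.order(cid)
    den = 1.0
    for cid in law.Ks:
        den *= S.get(cid, 0.0) ** law.order(cid)
    if den == 0.0:
        return math.inf if num > 0 else 0.0
    return num / den


def _saturation_terms(
    law: KineticLaw, S: Mapping[str, float], P: Mapping[str, float]
) -> tuple[float, float]:
    """(prod s^n, denominator) of the reversible law.

    s_i = S_i/Ks_i, p_j = P_j/Kp_j; the denominator is the literal
    prod(1+s_i^n_i) + prod(1+p_j^n_j) - 1 saturation polynomial.
    """
    prod_s = 1.0
    den_s = 1.0
    for cid, ks in law.Ks.items():
        s = S.get(cid, 0.0) / ks
        n = law.order(cid)
        prod_s *= s**n
        den_s *= 1.0 + s**n
    den_p = 1.0
    for cid, kp in law.Kp.items():
        p = P.get(cid, 0.0) / kp
        den_p *= 1.0 + p ** law.order(cid)
    return prod_s, den_s + den_p - 1.0


def reversible_rate(
    law: KineticLaw,
    E: float,
    S: Mapping[str, float],
    P: Mapping[str, float] | None = None,
) -> float:
    """Generalized reversible rate.

    r = kcat E * prod(S_i/Ks_i)^n_i * (1 - Q/K_eq) / D with the saturation
    denominator D = prod(1+s^n) + prod(1+p^n) - 1.  The sign of r equals
    the sign of (1 - Q/K_eq) and |r| <= kcat*E.  Evaluated in the expanded
    form kcat E (prod s^n - prod p^n * prod Kp^n/(K_eq prod Ks^n) ...) so
    that exhausted substrates (S=0, P>0) yield the correct negative rate.
    """
    if E < 0:
        raise ValueError("E must be non-negative")
    P = P or {}
    for cid, val in {**dict(S), **dict(P)}.items():
        if val < 0:
            raise ValueError(f"negative concentration for {cid!r}")
    prod_s, den = _saturation_terms(law, S, P)
    if law.k_eq is None:
        # irreversible: thermodynamic term is 1
        return law.kcat * E * prod_s / den
    # backward mass-action group: prod P^n / (K_eq * prod Ks^n)
    back = 1.0 / law.k_eq
    for cid, kp in law.Kp.items():
        back *= P.get(cid, 0.0) ** law.order(cid)
    for cid, ks in law.Ks.items():
        back /= ks ** law.order(cid)
    return law.kcat * E * (prod_s - back) / den


def rate_decomposition(
    law: KineticLaw,
    E: float,
    S: Mapping[str, float],
    P: Mapping[str, float] | None = None,
) -> tuple[float, float, float]:
    """Split the reversible rate into (eta_c, eta_s, eta_t).

    eta_c = kcat*E is the capacity, eta_s in [0,1] the saturation term,
    eta_t = 1 - Q/K_eq = 1 - exp(dG/RT) the thermodynamic term.  Their
    product reassembles the reversible rate exactly (for S > 0).
    """
    P = P or {}
    eta_c = law.kcat * E
    prod_s, den = _saturation_terms(law, S, P)
    eta_s = prod_s / den
    if law.k_eq is None:
        eta_t = 1.0
    else:
        q = _mass_action_ratio(law, S, P)
        eta_t = 1.0 - q / law.k_eq
    return eta_c, eta_s, eta_t


def haldane_keq(
    kcat_plus: float, kcat_minus: float, Ks: float, Kp: float
) -> float:
    """K_eq = kcat+ * K_P / (kcat- * K_S)."""
    if min(kcat_plus, kcat_minus, Ks, Kp) <= 0:
        raise ValueError("all Haldane arguments must be positive")
    return kcat_plus * Kp / (kcat_minus * Ks)


def enzyme_demand(
    law: KineticLaw,
    target_flux: float,
    S: Mapping[str, float],
    P: Mapping[str, float] | None = None,
) -> float:
    """Enzyme level (mmol/gDW) needed to carry ``target_flux``.

    E = r / (kcat * eta_s * eta_t); diverges as the mass-action ratio
    approaches K_eq.  Raises ThermodynamicallyInfeasible when the requested
    direction opposes (or sits at) the thermodynamic driving force.
    """
    if target_flux == 0:
        return 0.0
    per_enzyme = reversible_rate(law, 1.0, S, P)
    if per_enzyme == 0 or (per_enzyme > 0) != (target_flux > 0):
        raise ThermodynamicallyInfeasible(
            "thermodynamically infeasible demand: requested flux direction "
            "is not supported at these concentrations"
        )
    return target_flux / per_enzyme
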