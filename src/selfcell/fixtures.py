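"""Built-in reference networks and a random mass-conservative generator.

The fixture networks are the small worked examples used throughout the
package documentation and tests: a four-metabolite toy network whose
internal reactions r2, r3, r4 form a thermodynamic cycle, its internal
4x4 sub-network, and coarse-grained macromolecular-unit variants.
"""

from __future__ import annotations

import numpy as np

from .macro_units import UnitModel, UnitSpec, biomass_pseudoreaction
from .model import Compound, Network, Reaction

__all__ = [
    "TOY_WEIGHTS",
    "TOY_BIOMASS_FRACTIONS",
    "fixture_toy_network",
    "fixture_internal_network",
    "fixture_unit_network",
    "generate_random_conservative_network",
]

#: molecular weights of A-D (g/mol), the ratios of the biomass composition
#: in grams to its molar coefficients (e.g. 0.35 g / (0.35/150 mol)).
TOY_WEIGHTS = {"A": 150.0, "B": 100.0, "C": 100.0, "D": 200.0}

#: biomass composition, g per g biomass
TOY_BIOMASS_FRACTIONS = {"A": 0.35, "B": 0.15, "C": 0.30, "D": 0.20}


def _toy_compounds() -> list[Compound]:
    return [
        Compound(id=cid, molecular_weight=w, conc_min=1e-6, conc_max=0.1)
        for cid, w in TOY_WEIGHTS.items()
    ]


def _toy_internal_reactions() -> list[Reaction]:
    return [
        Reaction(id="r1", stoich={"A": -2, "B": 1, "C": 2}),
        Reaction(id="r2", stoich={"B": -2, "D": 1}),
        Reaction(id="r3", stoich={"C": -1, "B": 1}),
        Reaction(id="r4", stoich={"C": -2, "D": 1}),
    ]


def fixture_toy_network(with_biomass: bool = False) -> Network:
    """Four internal metabolites A-D and reactions r0-r6.

    r0 is the substrate input, r1-r4 are internal (r2, r3, r4 build a
    cycle), r5 excretes D and r6 (2A -> D) loses 100 g/mol to an implicit
    excreted by-product (``allows_mass_loss``).  With ``with_biomass`` a
    drain reaction built from the 0.35/0.15/0.30/0.20 g/g composition is
    appended and the fractions are attached to the compounds.
    """
    reactions = [
        Reaction(id="r0", stoich={"A": 1}, lower_bound=0.0, is_internal=False),
        *_toy_internal_reactions(),
        Reaction(id="r5", stoich={"D": -1}, lower_bound=0.0, is_internal=False),
        Reaction(
            id="r6",
            stoich={"A": -2, "D": 1},
            lower_bound=0.0,
            is_internal=False,
            allows_mass_loss=True,
        ),
    ]
    net = Network(compounds=_toy_compounds(), reactions=reactions)
    if with_biomass:
        for c in net.compounds:
            c.mass_fraction = TOY_BIOMASS_FRACTIONS[c.id]
        net.biomass_fractions = dict(TOY_BIOMASS_FRACTIONS)
        net.add_reaction(
            biomass_pseudoreaction(TOY_BIOMASS_FRACTIONS, TOY_WEIGHTS)
        )
    return net


def fixture_internal_network() -> Network:
    """The 4x4 internal sub-network (columns r1-r4 of the toy network)."""
    return Network(compounds=_toy_compounds(), reactions=_toy_internal_reactions())


def fixture_unit_network(
    variant: str,
    wA: float = 100.0,
    gamma2: float = 1000.0,
    gamma3: float = 1000.0,
    fB1: float = 0.5,
) -> tuple[Network, UnitModel]:
    """Coarse-grained macromolecular-unit networks.

    ``"two-unit"``: metabolite A plus units B1, B2; input r0, overflow r1
    and the two monomer-counting synthesis reactions (gamma2, gamma3 mol A
    per mol unit); unit weights are gamma*wA.  ``"two-unit-massfrac"``:
    the same network with synthesis columns expressed per gram of biomass
    flux, so the growth-mode kernel of M N has unit entries for both
    synthesis rates.  ``"three-unit"``: the toy network extended with
    drains A->B1, C->B2, D->B3 (mass conservative by construction).
    """
    if variant == "two-unit":
        compounds = [
            Compound(id="A", molecular_weight=wA, conc_min=1e-6, conc_max=0.1),
            Compound(id="B1", molecular_weight=gamma2 * wA),
            Compound(id="B2", molecular_weight=gamma3 * wA),
        ]
        reactions = [
            Reaction(id="r0", stoich={"A": 1}, lower_bound=0.0, is_internal=False),
            Reaction(id="r1", stoich={"A": -1}, lower_bound=0.0, is_internal=False),
            Reaction(id="r2", stoich={"A": -gamma2, "B1": 1}, lower_bound=0.0),
            Reaction(id="r3", stoich={"A": -gamma3, "B2": 1}, lower_bound=0.0),
        ]
        net = Network(compounds=compounds, reactions=reactions)
        model = UnitModel(
            units=[
                UnitSpec(id="B1", mass_fraction=fB1, monomer_stoich={"A": gamma2}),
                UnitSpec(
                    id="B2", mass_fraction=1.0 - fB1, monomer_stoich={"A": gamma3}
                ),
            ],
            metabolite_mass_budget=0.0,
        )
        return net, model

    if variant == "two-unit-massfrac":
        wB1 = gamma2 * wA
        wB2 = gamma3 * wA
        fB2 = 1.0 - fB1
        compounds = [
            Compound(id="A", molecular_weight=wA, conc_min=1e-6, conc_max=0.1),
            Compound(id="B1", molecular_weight=wB1),
            Compound(id="B2", molecular_weight=wB2),
        ]
        reactions = [
            Reaction(id="r0", stoich={"A": 1}, lower_bound=0.0, is_internal=False),
            Reaction(id="r1", stoich={"A": -1}, lower_bound=0.0, is_internal=False),
            Reaction(
                id="r2",
                stoich={"A": -fB1 / wA, "B1": fB1 / wB1},
                lower_bound=0.0,
            ),
            Reaction(
                id="r3",
                stoich={"A": -fB2 / wA, "B2": fB2 / wB2},
                lower_bound=0.0,
            ),
        ]
        net = Network(compounds=compounds, reactions=reactions)
        model = UnitModel(
            units=[
                UnitSpec(id="B1", mass_fraction=fB1, monomer_stoich={"A": gamma2}),
                UnitSpec(id="B2", mass_fraction=fB2, monomer_stoich={"A": gamma3}),
            ],
            metabolite_mass_budget=0.0,
        )
        return net, model

    if variant == "three-unit":
        net = fixture_toy_network()
        gammas = {"B1": ("A", 100.0), "B2": ("C", 100.0), "B3": ("D", 100.0)}
        for uid, (monomer, gamma) in gammas.items():
            net.add_compound(
                Compound(
                    id=uid,
                    molecular_weight=gamma * TOY_WEIGHTS[monomer],
                )
            )
            net.add_reaction(
                Reaction(
                    id=f"syn_{uid}",
                    stoich={monomer: -gamma, uid: 1},
                    lower_bound=0.0,
                )
            )
        model = UnitModel(
            units=[
                UnitSpec(
                    id="B1", mass_fraction=0.3, monomer_stoich={"A": 100.0}
                ),
                UnitSpec(
                    id="B2",
                    mass_fraction=0.3,
                    monomer_stoich={"C": 100.0},
                    gating="self",
                    k_syn=3.0,
                    k_m=0.01,
                    gating_metabolite="A",
                ),
                UnitSpec(
                    id="B3", mass_fraction=0.3, monomer_stoich={"D": 100.0}
                ),
            ],
            metabolite_mass_budget=0.1,
        )
        return net, model

    raise ValueError(
        f"unknown variant {variant!r}; choose one of "
        "'two-unit', 'two-unit-massfrac', 'three-unit'"
    )


def generate_random_conservative_network(
    l: int, q: int, seed: int
) -> Network:
    """Random network whose internal columns all satisfy w^T n = 0.

    Weights are sampled positive; for each column the last stoichiometric
    coefficient is solved from the others, so the mass balance closes to
    machine precision.  Deterministic under a fixed seed.
    """
    if l < 2:
        raise ValueError("need at least two compounds")
    if q < 1:
        raise ValueError("need at least one reaction")
    rng = np.random.default_rng(seed)
    weights = rng.uniform(10.0, 300.0, size=l)
    compounds = [
        Compound(id=f"c{i}", molecular_weight=float(weights[i]))
        for i in range(l)
    ]
    reactions = []
    for j in range(q):
        k = int(rng.integers(2, min(l, 4) + 1))
        support = rng.choice(l, size=k, replace=False)
        coefs = rng.uniform(0.5, 3.0, size=k - 1) * rng.choice(
            [-1.0, 1.0], size=k - 1
        )
        partial = float(np.dot(coefs, weights[support[:-1]]))
        last = -partial / float(weights[support[-1]])
        stoich = {
            f"c{support[i]}": float(coefs[i]) for i in range(k - 1)
        }
        stoich[f"c{support[-1]}"] = last
        reactions.append(Reaction(id=f"r{j}", stoich=stoich))
    return Network(compounds=compounds, reactions=reactions)
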