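import itertools

import numpy as np
import pytest
from scipy.linalg import null_space

from selfcell import (
    Compound,
    Network,
    Reaction,
    fixture_internal_network,
    fixture_toy_network,
)


@pytest.fixture
def toy_net() -> Network:
    return fixture_toy_network()


@pytest.fixture
def toy_net_biomass() -> Network:
    return fixture_toy_network(with_biomass=True)


@pytest.fixture
def internal_net() -> Network:
    return fixture_internal_network()


@pytest.fixture
def chain_net() -> Network:
    """Linear chain in -> X -> Y -> out, no cycles, fully mass conserved."""
    return Network(
        compounds=[
            Compound(id="X", molecular_weight=100.0),
            Compound(id="Y", molecular_weight=100.0),
        ],
        reactions=[
            Reaction(id="in", stoich={"X": 1}, lower_bound=0, is_internal=False),
            Reaction(id="x2y", stoich={"X": -1, "Y": 1}, lower_bound=0),
            Reaction(id="out", stoich={"Y": -1}, lower_bound=0, is_internal=False),
        ],
    )


def brute_force_efms(net, tol: float = 1e-9):
    """Independent elementary-flux-mode oracle by support enumeration.

    For every candidate support: the restricted stoichiometric matrix must
    have a one-dimensional kernel with no zero on the support, the kernel
    vector (possibly negated) must respect irreversibility, and no strict
    sub-support may qualify.
    """
    N = net.stoichiometric_matrix
    keep = [i for i, c in enumerate(net.compounds) if not c.is_external]
    N = N[keep, :]
    q = len(net.reactions)
    irreversible = [not r.reversible for r in net.reactions]
    candidates = []
    for size in range(1, q + 1):
        for support in itertools.combinations(range(q), size):
            sub = N[:, support]
            ns = null_space(sub)
            if ns.shape[1] != 1:
                continue
            v = ns[:, 0]
            if np.min(np.abs(v)) < tol:
                continue
            for sign in (1.0, -1.0):
                w = sign * v
                if all(
                    w[k] >= -tol
                    for k, j in enumerate(support)
                    if irreversible[j]
                ):
                    mode = np.zeros(q)
                    mode[list(support)] = w
                    candidates.append((frozenset(support), mode))
                    break
    supports = [s for s, _ in candidates]
    return [
        mode
        for s, mode in candidates
        if not any(o < s for o in supports)
    ]


def enumerate_lp_vertices(A_eq, b_eq, bounds):
    """Brute-force vertex enumeration of {x : A_eq x = b_eq, l <= x <= u}.

    Every vertex has n - rank(A_eq) active bound constraints; all
    combinations are solved and filtered for feasibility.
    """
    A_eq = np.asarray(A_eq, float)
    n = A_eq.shape[1]
    rank = np.linalg.matrix_rank(A_eq)
    n_active = n - rank
    lows = [b[0] for b in bounds]
    highs = [b[1] for b in bounds]
    constraints = [(j, lows[j]) for j in range(n)] + [
        (j, highs[j]) for j in range(n)
    ]
    vertices = []
    for combo in itertools.combinations(range(len(constraints)), n_active):
        rows = [np.eye(n)[constraints[k][0]] for k in combo]
        rhs = [constraints[k][1] for k in combo]
        M = np.vstack([A_eq] + rows) if rows else A_eq
        r = np.concatenate([b_eq, rhs])
        if np.linalg.matrix_rank(M) < n:
            continue
        x, *_ = np.linalg.lstsq(M, r, rcond=None)
        if np.max(np.abs(M @ x - r)) > 1e-8:
            continue
        if all(lows[j] - 1e-8 <= x[j] <= highs[j] + 1e-8 for j in range(n)):
            vertices.append(x)
    return vertices
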