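# Methods

This note documents the models, conventions, numerical choices and known
limitations of the package, in the order of the modelling ladder.

## Units and mass accounting

All specific quantities use gram dry weight (gDW) as the biomass basis:
fluxes mmol/gDW/h, concentrations mmol/gDW, molecular weights g/mol,
reaction energies kJ/mol, growth rates 1/h. The growth rate is the mass
balance of the cell,

    mu = w^T N r / 1000,

where the factor 1000 converts mg/gDW/h to g/gDW/h; it is applied inside
`growth_rate_from_fluxes` and the growth objective, never by callers.
Fully mass-conserved columns contribute nothing to mu; uptake adds mass,
excretion and annotated by-product losses remove it. On a network whose
compound rows are all balanced (plain FBA), w^T N r vanishes identically;
growth is then accounted through the rows exempt from balancing — external
unit compounds, or biomass-style drain pseudo-reactions (non-internal,
mass-losing, no products), whose flux equals mu by construction
(`fba.growth_coefficients`).

## The toy network

Four metabolites A–D with weights (150, 100, 100, 200) g/mol — the ratios
of the biomass composition in grams (0.35, 0.15, 0.30, 0.20) to its molar
coefficients (2.33e-3, 1.5e-3, 3e-3, 1e-3 mol/gDW). Reactions: input r0,
internal r1 (2A -> B + 2C), r2 (2B -> D), r3 (C -> B), r4 (2C -> D),
excretion r5 (D out), and r6 (2A -> D). r6 is not mass balanced as
written: 300 g of A become 200 g of D. It is flagged `allows_mass_loss`
and treated as excreting an implicit 100 g/mol by-product, which reduces
mu accordingly. The internal columns r1–r4 carry one cycle,
K = (0, -1, -2, 1).

Default flux bounds where a model gives none: ±1000 mmol/gDW/h for
reversible reactions, [0, 1000] for irreversible ones. They are run
configuration, not science; the unconstrained r3 optimum simply reports
whatever bound is set.

## Linear algebra

Numerical rank counts singular values above 1e-9 times the largest
(configurable); kernels are returned as orthonormal SVD bases, so cycle
vectors are defined up to sign — every consumer (sign tests, loop laws)
is sign-invariant.

Elementary flux modes (EFMs) are enumerated for small networks
(<= 20 columns after splitting reversible reactions) by the double
description method on the pointed cone {x >= 0 : N x = 0}, with
support-minimality filtering after each imposed row (the classical
tableau approach). Futile forward/backward two-cycles from the splitting
are dropped, each surviving support is verified to pin a one-dimensional
kernel, and modes are normalized to unit uptake flux when an exchange
uptake is in the support (first nonzero coordinate = +1 otherwise). An
independent brute-force oracle (exhaustive support enumeration with rank
and sign tests) backs the implementation in the test suite.

## FBA

LPs are solved with HiGHS (scipy.optimize.linprog). Degenerate optima are
tie-broken by a secondary lexicographic minimization of total flux at the
fixed optimal objective, so results are reproducible; detected degeneracy
is flagged in the solution manifest. Total-flux minimization splits each
flux into non-negative forward/backward parts. Pareto fronts use the
ε-constraint scheme (default 20 grid points) between the two
single-objective optima; infeasible grid points are skipped with a
warning.

## Thermodynamics

Energies follow dG = dG0' + RT N'^T x over the internal columns N', with
x = ln c. Defaults: RT = 8.315e-3 * 300 = 2.4945 kJ/mol (T configurable;
standard-condition tables assume 298 K), log-concentration window
ln[1e-6, 0.1] mmol/gDW unless the compound carries explicit bounds.
K_eq and dG0' interconvert via dG0' = -RT ln K_eq.

Loopless FBA implements the big-M MILP: binaries z_i couple the flux sign
to the dG sign (z=1: r >= 0, dG in [-M, -eps]; z=0: r <= 0, dG in
[eps, M]) and K^T dG = 0 removes net cycle flux. Defaults eps = 0.1
kJ/mol, M = 1e4 kJ/mol. Strict inequalities are LP-represented as
<= -eps. The big-M form cannot force dG = 0 on zero-flux reactions inside
a cycle; instead of a special-cased MILP, feasibility of a flux map with
zeros is established post hoc by the concentration LP, in which zero-flux
reactions are simply unconstrained. A warning is raised only when a
flux-carrying reaction's |dG| is clamped at M.

Sign patterns for the concentration-coupled constraints and for MDF are
taken from a supplied flux map, mirroring their intended use downstream
of an FBA/loopless solution. MDF maximizes the margin B subject to
-sign(r_i)·dG_i >= B; the witness x is returned alongside the energies.

## Enzyme constraints

Capacity: |r_i| <= kcat_i E_i for every reaction with a kcat annotation,
with the absolute value realized by forward/backward splitting; a shared
budget Sum E_i <= E_total and optional per-enzyme caps. Cost
minimization uses weights w_i (default 1). When a model carries no kcat,
the documented stand-in 1.8e6 1/h is used — the order of magnitude
obtained from ~2000 transporter copies in a 1e-12 gDW cell carrying
6 mmol/gDW/h.

## Rate laws

The generalized reversible law converts n_i molecules of S_i into n_j
molecules of P_j:

    r = kcat E * prod(s_i^n_i) * (1 - Q/K_eq) / D,
    D = prod(1 + s_i^n_i) + prod(1 + p_j^n_j) - 1,

with s = S/K_S, p = P/K_P, and Q the mass-action ratio. The "-1" in D is
implemented literally; molecularities must be positive integers and enter
both the saturation polynomial and Q. The factorization eta_c = kcat E,
eta_s = prod(s^n)/D in [0,1], eta_t = 1 - Q/K_eq = 1 - exp(dG/RT) is
exact, and the Haldane relationship K_eq = kcat+ K_P / (kcat- K_S) is
either enforced (1e-9 relative) or used to derive K_eq. The rate is
evaluated in expanded form so exhausted substrates (S = 0, P > 0) give
the correct negative rate. Binding constants carry the mmol/gDW
concentration units used everywhere else. Allosteric effector terms and
temperature dependence of kcat are out of scope.

Enzyme demand inverts the law, E = r/(kcat eta_s eta_t), and raises a
typed error when the requested direction opposes the driving force; the
demand diverges as Q -> K_eq.

## Macromolecular units

The biomass pseudo-reaction stores coefficients on the mmol basis
(1000·fraction/weight), so its flux variable is mu in 1/h and the drained
mass is exactly 1 g/gDW per unit flux. The M-matrix is the outer-product
form M = I - c w^T / 1000 (the only dimensionally consistent reading of
the growth-dilution correction), giving M N r = N r - mu c.

The reduced two-unit allocation model puts the cell's mass into an
uptake sector B1 (r0 = k1 B1) and a synthesis sector B2 (r2 = k2 B2),
all rates as mass fluxes in g/gDW/h with the metabolite's mass fraction
negligible. Steady state forces r1 = r0 - r2 (overflow) and mu = r2;
allocations with r1 < 0 would require re-importing the overflow product
and are flagged infeasible. The optimum sits at the kink k1 B1 = k2 B2:
B1* = k2 B/(k1+k2), mu* = k1 k2 B/(k1+k2) — hyperbolic in the uptake
gain (substrate limitation sweeps) and linear in the available biomass
(heterologous-burden sweeps). Defaults k1 = 3, k2 = 1.5 1/h put mu* at
1.0 1/h, a typical fast-growth figure; the scan grid default is 401
points, and a golden-section continuous oracle backs the scan in tests.

## The self-contained model

The three-unit reference model extends the toy network with drains
A -> B1, C -> B2, D -> B3 (100 monomers per unit; unit weights are
100 × the monomer weight, so the columns conserve mass exactly). The
wiring of which metabolite feeds which unit is a package choice. Closure:
metabolites C_total = 0.1 g/g (10% of cell mass), B1 = 0.1 g/g fixed
machinery plus the enzyme mass (enzyme weight 1e4 g/mol, configurable),
B2 free, B3 the inert remainder; all four sum to 1. B2 is
self-replicating: its synthesis capacity k_syn · (M/K_M) · B2 (gating
metabolite A, k_syn = 3 1/h, K_M = 0.01 mmol/gDW) must cover the
synthesis demand mu·(B1 + E_mass + B2); B3 closes the balance and is
unconstrained. Metabolite concentrations have a floor of 1e-6 mmol/gDW
(a concentration cannot be zero) and a ceiling of 1.0 mmol/gDW — the
ceiling must leave the 10% mass budget reachable (0.1 mmol/gDW would cap
the pool at 0.055 g/g). Kinetic defaults: kcat = 1.8e6 1/h everywhere,
binding constants 0.01 mmol/gDW, equilibrium constants driving the
network from A toward D (K_eq1 = 10, K_eq2 = 1e4, K_eq3 = 10) with the
cycle identity K_eq4 = K_eq2·K_eq3² respected; r0, r5 and r6 are
irreversible. Enzyme budget E_total = 1e-5 mmol/gDW, sized so that it
binds near 10 mmol/gDW/h of uptake.

Growth maximization is solved all-at-once over the scaled variables
(enzyme shares, metabolite mass shares, B2): a damped least-squares pass
finds a steady state, a feasibility ladder pushes the growth rate up by
pinning mu at increasing targets (coarse steps of 0.3 1/h, then 10
bisections), and a constrained SLSQP step polishes the best point. The
ladder is the workhorse because the steady-state manifold is thin and
cold-started SQP stalls on it; pinning mu turns maximization into a
sequence of well-conditioned root problems. Runs are multistart (default
4 seeded starts plus optional warm starts) and deterministic under a
fixed seed. Every candidate is re-verified by an independent checker
(kinetic rates, steady-state residuals, budgets, closure, mu
consistency) before acceptance — no solver claim is trusted.

Supply/demand reports partition one metabolite's steady state into
supply, demand, biomass-drain and dilution mu·c terms. EFM comparisons
treat the unit compounds as drains (unbalanced rows), scale each mode to
the solution's uptake and report the nearest mode by normalized distance
over the metabolic fluxes.

## What the synthetic defaults do and do not show

The fixture networks are the printed reference matrices and reproduce
their linear-algebraic and thermodynamic quantities exactly. The kinetic
and allocation parameters of the unit and self-contained models, by
contrast, are package defaults chosen once for physiological
plausibility; the corresponding tests assert structural properties
(self-consistency, budgets, monotonicity, saturation, proximity to flux
modes), not literal curve values. Random mass-conservative networks for
property tests solve the last stoichiometric coefficient of each column
from the others, so w^T N = 0 holds to machine precision — they exercise
conservation laws, not realistic network topology (no blocked reactions,
no realistic degree distribution). Passing tests certify the mathematics
of the methods, not predictions for any real organism.

## Known limitations

- EFM enumeration is deliberately guarded to tiny networks; genome-scale
  enumeration belongs to dedicated tools.
- The self-contained optimizer returns the best verified local optimum of
  a multistart; there is no global optimality certificate.
- SBML/COBRA formats, flux variability analysis, quadratic objectives,
  dG0' estimation from compound structures, and time-course integration
  of the concentration ODEs are out of scope.
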