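# selfcell

Constraint-based modelling of cellular growth, from plain flux balance
analysis (FBA) to self-contained kinetic cell models, on small plain-text
networks.

The package is aimed at students and modellers who want to see, on a
network small enough to check by hand, how the standard ladder of
constraint-based methods fits together:

1. **Mass conservation.** Every reaction column *n* of the stoichiometric
   matrix *N* (compounds × reactions, substrates negative) should satisfy
   *wᵀn = 0* with *w* the molecular weights; deliberate by-product losses
   are annotated, everything else is audited.
2. **FBA.** Steady state *N r = 0* with bounds and a linear objective,
   solved as an LP; total-flux minimization and ε-constraint Pareto fronts
   between two objectives.
3. **Thermodynamics.** Reaction energies ΔG = ΔG⁰′ + RT·N′ᵀx (x the log
   concentrations) must oppose flux, ΔG·r < 0, and obey the loop law
   KᵀΔG = 0 on every internal cycle K. Four mechanisms are implemented:
   loop-law checks, big-M MILP loopless FBA, the sign-vector cycle test
   |s_cᵀs_f| < s_cᵀs_c, and concentration-coupled constraints, plus the
   max-min driving force (MDF) program that maximizes the smallest |ΔG|
   along a flux map.
4. **Enzymes.** Capacity constraints |r| ≤ kcat·E with a shared proteome
   budget ΣE ≤ E_total, enzyme-cost minimization, and copy-number/kcat
   conversions.
5. **Macromolecular units.** Instead of one biomass pseudo-reaction, the
   cell is split into mass sectors (uptake machinery B₁, self-replicating
   B₂, inert B₃); growth follows from mass conservation alone,
   μ = wᵀN r / 1000, and steady states solve (I − c wᵀ)N r = M N r = 0.
6. **Kinetics and the self-contained model.** Reversible rate laws
   r = kcat·E·η_s·η_t (saturation × thermodynamic driving force, Haldane
   consistent) turn the flux cone into a kinetic model whose only external
   input is the substrate concentration; growth maximization over enzyme,
   metabolite and sector allocations is a smooth NLP.

Units are fixed package-wide: fluxes mmol/gDW/h, concentrations mmol/gDW,
weights g/mol, energies kJ/mol, growth 1/h (the g↔mmol factor 1000 is
applied inside the growth-rate helpers).

## Worked example

The built-in toy network has four metabolites A–D (150, 100, 100,
200 g/mol), an input r0, internal reactions r1–r4 (r2, r3, r4 form a
cycle), an excretion r5 and a by-product shortcut r6 (2A → D, losing
100 g/mol). With the biomass composition 0.35 g A + 0.15 g B + 0.30 g C +
0.20 g D per gram of cells:

```python
import selfcell as sc

net = sc.fixture_toy_network(with_biomass=True)
sol = sc.solve_fba(net, sc.Objective.maximize("biomass"), fixed={"r0": 10.0})
print(sol.objective_value)          # 1.5000000000000002
print(sol.fluxes.round(4).to_string())
```

```
r0         10.00
r1          3.25
r2          0.50
r3          0.00
r4          1.00
r5          0.00
r6          0.00
biomass     1.50
```

The growth rate 1.5 1/h is exactly the mass bound: 10 mmol/gDW/h of a
150 g/mol substrate carries 1.5 g/gDW/h, and the optimal flux map wastes
none of it (r5 = r6 = 0). The biomass flux *is* μ because the drain
coefficients are mass fractions over molecular weights (0.35/150 =
2.33·10⁻³ mol A per gram of biomass, and so on).

The same network shows why thermodynamics matters: maximizing r3 without
energy constraints pins it at its bound (1000) by spinning the r2/r3/r4
cycle, while `sc.loopless_fba` returns the physically meaningful optimum
r3 = 1:

```python
sc.solve_fba(net, sc.Objective.maximize("r3"), fixed={"r0": 1}).objective_value
# 1000.0
sc.loopless_fba(net, sc.Objective.maximize("r3"), fixed={"r0": 1}).objective_value
# 1.0000010000000004
```

The capstone solver needs nothing but the substrate level:

```python
model = sc.default_selfcontained_model()
sol = sc.solve_selfcontained(model, S_ext=10.0, starts=4, seed=1)
sol.mu                      # ~1.586, at the mass bound of its own uptake
sol.meta["allocation"]      # {'C': 0.1, 'B1': 0.1001, 'B2': ..., 'B3': ...}
```

A `selfcell` command-line tool wraps these operations (`selfcell validate`,
`fba`, `loopless`, `mdf`, `ecfba`, `units`, `selfcontained`, `efm`,
`pareto`); models are JSON files documented in `selfcell/io.py`.

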