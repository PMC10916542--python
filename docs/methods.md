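# Methods

## Model and assumptions

The package builds a steady-state, community-scale flux balance model from
single-strain genome-scale models. Three constraint families define it:

1. **Global mass balance.** All sub-models, link reactions and shared
   exchanges are merged into one stoichiometric matrix S_cul with
   S_cul·v = 0 and 0 ≤ v ≤ v_u. Every reversible reaction is first split
   into an irreversible forward/`_reverse` pair (a parent with bounds
   (lb < 0, ub) becomes (0, ub) plus a negated-stoichiometry sibling with
   bounds (0, −lb)), so all fluxes are nonnegative and net flux is forward
   minus reverse. Splitting provably preserves the feasible net-flux
   polytope; this is property-tested against a signed-variable LP oracle.

2. **Per-strain enzyme pools.** Each strain x carries one inequality
   Σ_i v_xi·MW_xi/kcat_xi ≤ ENZ_x over its enzyme-annotated reactions,
   with ENZ_x = ptot·f·σ. Units: kcat in h⁻¹, MW in g mmol⁻¹ (numerically
   kDa), fluxes in mmol gDW⁻¹ h⁻¹, so the cost terms and the budget are
   both in g enzyme per gDW. Strains never share a pool — sub-models stay
   independently constrained. One cost term per reaction: an enzyme
   catalyzing several reactions contributes one term per reaction, and an
   isozyme set is represented by whatever single (kcat, MW) the table
   author chose. Reactions without valid kinetics are either excluded from
   the sum (default, the treatment used for heterologous reactions lacking
   data) or given the strain-median kcat and MW (`fallback="default_kcat"`).
   Exchange, link and biomass reactions never carry cost.

3. **Modular interaction scale.** Inter-strain flow passes exclusively
   through shared pool metabolites. For normalized inoculation fractions
   m_x (Σ m_x = 1), each (strain, shared metabolite) pair gets a reversible
   link pair with stoichiometry {1.0 strain-side, 1/m_x shared-side}. The
   shared metabolite's balance row then forces paired link fluxes of two
   strains into the ratio m : n. Normalization is essential: raw ratios
   (2,1) and (4,2) must produce identical models, otherwise sweep values
   would depend on arbitrary ratio scaling. Links are created only for
   metabolites the user lists as shared (the curated cross-feeding design),
   not for every extracellular metabolite. No combined community biomass
   reaction exists; growth enters only through per-strain biomass reactions.

**Unit interpretation of sub-model fluxes.** The link coefficient 1/m_x sits
between a sub-model flux and the shared pool, so a strain's community-side
throughput equals its sub-model flux divided by its fraction, while its
enzyme budget is fixed per sub-model. The equations are implemented exactly
in this form; whether sub-model fluxes are per-gDW-of-strain or
community-total quantities is an interpretation left to the reporting layer,
and only shared-side (objective) fluxes are asserted in tests. One
consequence worth knowing: at a continuous optimum the shared throughput
equals the *sum* of module capacities (pool/cost), attained by allocating
fractions proportional to capacity, and shrinking a strain's fraction
relaxes its constraint. The limit of a vanishing fraction is therefore not
"strain absent" — absence is expressed by omitting or closing the strain's
links, which the API enforces (zero fractions are rejected with that
guidance).

## The linear program

Pure LP throughout — the constraint set contains no integer structure.
Variables are the sorted reaction ids (so repeated builds are bit-identical,
verified by matrix hashing); the solver is scipy's HiGHS backend with
feasibility/optimality tolerance 1e-9. Every optimal solution is re-checked
with independent numpy arithmetic (mass-balance residuals, bounds, enzyme
rows) and the report is attached to the result; corrupted solutions fail
naming the violated row. Reported flux distributions come from a
parsimonious refinement (minimize Σv subject to the objective staying
within (1−1e-9) of the optimum), which collapses alternate-optima
degeneracy; objective values are always taken from the first solve.
Infeasible points in sweeps are kept with value 0 and a status flag so
ratio grids stay rectangular. The LP can be exported in MPS format.

## Exact oracle

Tests verify the solver against an independent exact-arithmetic route: the
same constraint system rebuilt over `fractions.Fraction` and solved with a
Bland-rule primal simplex (equalities passed as opposing inequality pairs,
making the all-slack basis feasible; Bland's rule guarantees termination on
the resulting degenerate systems). Float coefficients enter the exact layer
as their shortest round-tripping decimal, so a model built from round
constants like 0.1 is represented as 1/10 exactly. A brute-force
enumeration of basic solutions over active constraint subsets cross-checks
the simplex route on systems of ≤ 12 variables; the simplex oracle itself
refuses systems beyond toy size (64 variables) — it is a verification tool,
not a solver.

## Toy models: what they emulate, what they do not

The bundled toys stand in for published case-study GEMs and were sized so
the whole test suite runs in seconds on one CPU:

* **TOY2** (18 LP variables): a two-strain linear pathway split, upstream
  cost 0.5 / pool 1, downstream cost 1.0 / pool 1, shared glucose cap
  10 mmol gDW⁻¹ h⁻¹. Shared product flux is min(2/m, 1/n, 10); grid optimum
  3.0 at 2:1, 1:1 gives 2.0.
* **TOY3** (27 variables): modules A and B feed C, which condenses both
  intermediates 1:1; costs (0.5, 1/3, 1.0) give capacities (2, 3, 1) and a
  unique optimum 6.0 at 2:3:1 over the 13-point grid. The glucose cap is 20
  so that the enzyme pools, not substrate supply, bind at the optimum (a
  cap of 10 would truncate the optimum into a degenerate plateau). Merged
  variants ("AB", "BC", "AC") put two module capacities under one pool;
  because 1/(x+y) ≤ 1/x + 1/y, the three-strain split always beats them —
  the mechanism behind "give each critical reaction its own module".
* **Overflow toy** (6 variables): respiration (26 ATP/glc, cost 0.1) vs
  fermentation (12 ATP/glc + 2 acetate, cost 0.02), pool 1. Acetate is zero
  until uptake exceeds pool/respiration-cost = 10; at uptake 20 the binding
  vertex is (respiration 7.5, fermentation 12.5), acetate 25, ATP 345.

These toys have 100% enzyme coverage, round-number kinetics and single-step
"pathways"; they do not emulate genome-scale redundancy, cofactor balancing,
realistic kcat distributions or partial enzyme coverage. Passing tests
therefore demonstrate the correctness of the constraint machinery and the
qualitative allocation phenomenology, not quantitative accuracy on real
organisms — that requires user-supplied GEMs and curated kinetic tables.

## Ratio grids and campaigns

The default two-strain grid is {9:1, 4:1, 3:1, 2:1, 1:1, 1:2, 1:4, 1:9};
the default three-strain grid has 13 points (the 1:1:1 center, single- and
double-increment permutations, and the 2:3:1 / 3:2:1 / 1:2:3 family). Both
are overridable. `compare_strategies` runs each allocation strategy over
its grid twice — with enzyme rows and with all pool rows removed ("basic
GEM" mode). The stoichiometry-only mode hits the substrate cap regardless
of allocation, so it cannot separate strategies the enzyme-constrained mode
separates; this contrast is asserted in the tests.

Yield metrics: mass yield (v_p·MW_p)/(v_s·MW_s) in g/g; signed relative
estimation error (sim − exp)/exp; NRMSE = sqrt(mean((sim−exp)²)) / (max(exp)
− min(exp)). The mean divides by the number of grid points — the standard
RMSE convention — and the denominator is the experimental range.
Experimental series are user-supplied CSV; the tool never digitizes figures.

## Numerical and design choices

* Knockouts zero a reaction's bounds rather than delete it (audit trail and
  re-activation); deletion is available behind a flag. Gene-level knockouts
  evaluate and/or rules with the standard COBRA convention ("and" =
  complex, "or" = isozymes), delegated to cobrapy's GPR parser.
* Namespacing appends `@tag` to every id; the pre-namespace id is kept as
  `base_id` for kinetic-table matching. SBML export rewrites `@` to `__`
  for SId-charset compliance (origin is preserved in notes), so byte-level
  id round-trips are a JSON property; SBML round-trips are exercised on
  pre-namespace models.
* `_reverse` is the canonical reverse-direction suffix; a pre-existing
  colliding id is an error, never silently renamed.
* Kinetic tables declare kcat units per row or via the header; per-second
  values are converted to h⁻¹ at load time. Nonpositive entries and
  duplicate reaction ids are rejected with the offending line named.
* Pool parameters are config values; the package hard-codes no organism
  constants.
* Tolerances: LP feasibility 1e-9 (floating solutions sit within ~1e-12 of
  the constraint surfaces, so a tolerance of exactly 0 would reject valid
  solutions); oracle agreement asserted at 1e-6, reflecting accumulated
  float error across build/solve, not solver quality.

## Known limitations

No dynamic (time-course) community simulation, no spatial structure, no
flux variability analysis or sampling, no thermodynamic constraints, and no
kcat calibration — kinetic tables are consumed as prepared. The unit
question above means absolute per-strain flux magnitudes at extreme ratios
should be interpreted with care; shared-side objective values are the
quantities the method is designed to rank.
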