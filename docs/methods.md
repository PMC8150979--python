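# Methods

Models, assumptions, parameter choices and numerical details for the
`gemsmith` package. Nothing in this document claims results beyond what the
test suite and `scripts/acceptance.py` actually compute.

## 1. Model representation and flux balance analysis

A `MetabolicModel` is a plain container of metabolites (id, name,
compartment), reactions (stoichiometry mapping, bounds, optional GPR rule,
kind ∈ {enzymatic, transport, exchange, pseudo}) and gene labels, with one
designated objective (biomass) reaction. `validate_model` enforces the
invariants the solvers assume: referenced metabolites/genes exist, bounds
are ordered, exchange reactions touch exactly one metabolite, the objective
exists, and ids are unique.

**FBA** (`solve_fba`) maximizes the objective flux subject to `S·v = 0` and
the bounds, via `scipy.optimize.linprog` with the HiGHS solver. Conventions:

* **Exchange sign**: positive flux exports, negative imports. A *medium* is
  a mapping of exchange-reaction id → maximum uptake rate (mmol/gDW/h);
  applying it sets each listed exchange's lower bound to `−rate` and closes
  the uptake direction (`lb = 0`) of every unlisted exchange. Export bounds
  are untouched.
* **Statuses**: `optimal`, `infeasible`, `unbounded`; solutions report the
  objective value and a full flux vector.
* **Flux snapping**: fluxes with magnitude below `FLUX_ZERO_TOL = 1e-6`
  are reported as exactly zero; solver round-off below that level carries
  no information at the problem scales used here.

`prune_dead_ends` iteratively removes non-exchange, non-pseudo reactions
that involve a metabolite used by exactly one reaction (which therefore can
never carry steady-state flux), and refuses to prune the objective.

**Oracle**: for models with ≤ 8 reactions the tests enumerate basic
solutions directly — fix `n − rank(S)` fluxes at bound combinations, solve
the remainder by least squares, keep feasible points — and require the LP
optimum to agree to `1e-9`.

## 2. GPR rules and paralogues

GPR rules are boolean trees over gene ids with `and`/`or`; the parser gives
`and` higher precedence than `or` and is case-insensitive on operators. A
rule evaluates against a set of deleted genes. Disjunctive normal form is
computed with absorption of supersets and a cap of 1024 terms (above the
cap DNF returns `None`; the cap bounds worst-case exponential blow-up on
pathological rules). A reaction "has paralogues" when its DNF contains ≥ 2
alternative gene sets; if the DNF is capped, the presence of any `or` node
is used as a conservative fallback. The `paralogue_fraction` of a model is
the fraction of GPR-bearing reactions with alternatives.

Tests check DNF semantics against direct evaluation over *all* deletion
subsets of randomly generated trees (hypothesis), so the normal form is
never trusted on its own authority.

## 3. Homology filtering and draft reconstruction

A homology hit carries query, subject, percent identity, alignment length
and e-value. `FilterCutoffs` defaults — `max_evalue = 1e-50`,
`min_alignment_length = 90`, `min_identity = 40.0` — are applied
*inclusively* (a hit at exactly the cutoff passes). `filter_orthologs`
keeps a (template gene, target gene) pair only when a passing hit exists in
**both** search directions; this bidirectional requirement is what removes
one-way decoy hits.

`draft_from_template` rewrites each template reaction's GPR by substituting
every template gene with the OR of its mapped target genes; genes with no
mapping become unsatisfiable leaves. Reactions whose rewritten rule cannot
be satisfied are dropped; `transfer_nongene_reactions` then copies over all
exchange/pseudo/GPR-less reactions, which carry no genetic evidence either
way.

`genomic_coverage(n_model_genes, n_genome_genes)` is the percentage of
genome genes captured by the model, rounded to one decimal.

## 4. Gap-filling

`gap_fill(draft, template, objective, medium, epsilon=1e-3, big_m=1000)`
solves a MILP (HiGHS): continuous fluxes for draft ∪ candidate reactions,
one binary indicator per candidate, `S·v = 0`, `y_j·lb_j ≤ v_j ≤ y_j·ub_j`
via big-M rows, objective flux ≥ `epsilon`, minimize `Σ y`. Infinite bounds
are clipped to ±`big_m`, so `big_m` must exceed any flux the toy problems
need (their natural scale is ≤ 10). `epsilon = 1e-3` demands biologically
meaningful growth while staying far above solver tolerance. Ties at the
optimal cardinality are broken deterministically: all size-`k` candidate
combinations are checked in lexicographic order when `C(n, k) ≤ 2000`,
otherwise the MILP's own solution is kept. If the full template itself
cannot grow, `UnfillableError` reports the biomass precursors that cannot
be produced.

**Oracle**: for ≤ 12 candidates, exhaustive subset search by increasing
cardinality provides the true minimum size; tests also verify minimality
directly (removing any chosen reaction breaks growth).

## 5. Reversibility from Gibbs free energies

`assign_reversibility` maps a ΔG' table onto bounds with a ±30 kJ/mol
threshold, inclusive on both sides: `ΔG ≤ −30` ⇒ forward-only `(0, ub)`;
`ΔG ≥ +30` ⇒ reverse-only `(lb, 0)`; `−30 < ΔG < 30` ⇒ reversible
`(−1000, 1000)`. Reactions with no ΔG estimate are left untouched and
returned in a manual-curation list. The rule is idempotent. The 30 kJ/mol
band is the conventional "clearly irreversible" margin for transformed
reaction energies at physiological conditions; the ±1000 default bound is
the package-wide proxy for "unconstrained".

## 6. Biomass assembly and energetics

`monomer_fractions` converts DNA/RNA/protein sequences into mole fractions
(DNA pairing counts both strands; ambiguous residues are rejected).
`build_biomass` assembles a biomass pseudo-reaction from macromolecular
mass fractions and monomer fractions, plus a GAEC term: `gaec` mmol ATP +
water → ADP + phosphate per gram of biomass. NGAM is a separate
ATP-hydrolysis reaction whose bounds are *fixed* at the maintenance flux
(`lb = ub = ngam`), i.e. the cell must spend that ATP whether or not it
helps.

`predicted_growth(model, ngam, gaec, medium, current_gaec=…)` rebuilds the
biomass ATP term at the requested GAEC before solving; `current_gaec` must
state the GAEC already embedded in the model's biomass reaction (the toy
template ships with 2.0) so coefficients are replaced, not stacked.

`calibrate_energetics` fits GAEC for each NGAM on a grid so predicted
growth matches a target rate: bisection on GAEC over `(0, 10000)`, 60
iterations, relative tolerance `1e-4` on growth. Growth is strictly
decreasing in GAEC on the ATP-limited branch, so bisection converges to the
rightmost crossing; NGAM values whose maximum attainable growth is below
the target report `NaN`. The function also returns a deviation surface over
an (NGAM, GAEC) grid and a trade-off table of fitted GAEC per NGAM.

### Closed form for the toy

The toy template's optimum is, per unit glucose uptake `q`:

```
mu = max(0, min((3·q − ngam) / (1 + gaec),  2·q))
```

The first branch is the ATP balance (3 ATP per glucose through the trunk,
`ngam` burned by maintenance, `1 + gaec` ATP per unit biomass — 1 from the
amino-acid-synthesis step, `gaec` from biomass hydrolysis); the second is
the carbon ceiling. `closed_form_growth` implements it and every growth
assertion in the tests is checked against it rather than against numbers
read off a solver run.

**Validity caveat — low-GAEC inversion.** The carbon branch `2q` assumes
surplus ATP can be disposed of freely. With NGAM as a *fixed-flux* reaction
the toy has no free ATP sink: below the kink
`gaec* = (3q − ngam)/(2q) − 1`, surplus ATP must be burned through the
ATP-consuming shikimate branch, which also costs carbon, and optimal growth
there is *lower* than the closed form and **increases** with GAEC. A
dedicated test pins this regime with a hand derivation
(`q = 1, ngam = 0.3`: `mu(0) = 1.3 < mu(0.35) = 2.0`). Calibration and the
acceptance monotonicity sweep therefore operate at `gaec ≥ 0.5`, inside
the ATP-limited branch.

## 7. Yield estimation from cultivation data

The generator produces exponential growth `x(t) = x0·e^{mu·t}` with glucose
`g(t) = g0 − Y·(x(t) − x0)`, truncated where glucose would go negative,
with i.i.d. Gaussian noise (sd `sigma`) on the glucose readings of each
replicate. `estimate_yield` pools all replicate samples and fits ordinary
least squares of glucose on biomass **with an intercept**; the magnitude of
the slope is the yield `Y` (mmol glucose per gDW) and its standard error
uses `n − 2` degrees of freedom.

The intercept is essential: anchoring the fit through the (noisy) first
sample of each replicate, or regressing deltas from it, correlates the
residuals and understates the standard error — measured 3-SE coverage drops
to ≈ 94% in that variant, versus ≈ 99% for the intercept fit (the
theoretical ceiling for `P(|t| ≤ 3)` at 16 dof is 99.15%). Windows with
fewer than 3 samples raise; replicates whose glucose is not non-increasing
trigger a warning but are still used.

Default generator parameters (`ToyConfig`): `yield = 24.7` mmol/gDW,
`mu = 0.09` 1/h, `x0 = 0.02` gDW/L, `g0 = 60` mmol/L, `sigma = 0.3`
mmol/L, `dt = 6` h, `horizon = 72` h, 3 replicates. These give ~13 samples
per replicate before glucose depletion and a noise level (~0.5% of `g0`)
at which the estimator is informative but the noise is not negligible.
`sigma` was fixed before the coverage experiments and not adjusted
afterwards.

## 8. Essentiality

`single_gene_deletion` solves the wild type once, then for each gene
evaluates every GPR with that gene deleted, closes (bounds to 0) reactions
whose rule is false, and re-solves. A gene is essential when the mutant is
infeasible or its growth ratio is ≤ 1/3 of wild type, with a `+1e-6`
slack so a mutant at exactly one third classifies as essential despite
solver round-off. The 1/3 threshold is the conventional "severe growth
defect" cutoff for deletion screens.

**Oracles**: (a) a rebuild oracle constructs, per gene, a fresh model with
the GPR-false reactions removed and compares ratios to `1e-6`; (b) when
`cobra` is installed, the model is exported to SBML and cobra's
`single_gene_deletion` must agree to `1e-6`. cobra is never used in the
implementation itself.

`cross_model_comparison` matches essential genes across two models through
an ortholog mapping, reporting shared, model-specific and unmapped genes.

## 9. FSEOF

`fseof_scan(model, biomass, product, medium, n_steps=10, max_fraction=0.9)`
first finds the product's flux `v0` while maximizing biomass and its
theoretical maximum `vmax`, then enforces the product exchange *as an
equality* at `n_steps` evenly spaced levels from `v0` to
`max_fraction·vmax`, maximizing biomass at each. Per reaction, the slope of
flux against enforced product flux is a centered least-squares fit over the
trajectory; a reaction is an **overexpression** target when its flux
increases sign-consistently (slope > 0, no step moving against it beyond
tolerance), **downregulation** when the reverse. `max_fraction = 0.9`
keeps the final point strictly inside the feasible region so biomass stays
positive. `shared_targets` intersects target sets across products and
partitions them into shared and product-specific groups.

## 10. Synthetic ecosystem generator

`make_ecosystem(seed, config)` produces, deterministically per seed: the
template model, forward/reverse hit tables (true pairs passing all cutoffs,
degraded genes failing exactly one chosen cutoff, dropped genes absent,
unidirectional decoys that the bidirectional filter must remove), a ΔG
table exercising every regime including exact boundary values, cultivation
time courses, and a `Truth` record with the expected ortholog pairs, draft
and final reaction sets, gap-fill additions and essential genes of the
final model — every downstream stage is testable against recorded truth
rather than against its own output.

The designed core has 28 reactions (glycolysis-like trunk to pyruvate and
ATP, a pentose-phosphate-like branch, a shikimate-like chain to two
products, amino-acid synthesis, biomass, NGAM, transporters and
exchanges); `n_reactions` ∈ [28, 80] pads with inert linear appendices
that never affect growth. GPR structure is designed: isozyme pairs (OR),
complexes (AND), giving a known paralogue count. Scope limits: single
compartment pair (external/cytosol), no charge or formula balancing, noise
only on cultivation glucose readings, hit-table scores are constructed
(not drawn from an alignment model).

## 11. I/O

Native JSON round-trips the full model exactly. SBML is written as Level 3
Version 1 with the FBC v2 package (via `python-libsbml`): species,
compartments, bounded reactions, gene products and GPR associations,
objective. Reaction *kind* is not representable in FBC and is re-derived
heuristically on read (exchange by boundary species, transport by
cross-compartment stoichiometry), so round-trip tests compare everything
except kinds. Only the subset of SBML needed for constraint-based analysis
is supported — no kinetics, units, annotations or groups.

## 12. Numerical choices, summarized

| Constant | Value | Where | Rationale |
|---|---|---|---|
| `FLUX_ZERO_TOL` | 1e-6 | FBA | snap solver round-off to zero |
| default bound | ±1000 | models | "unconstrained" proxy, > any toy flux |
| gap-fill `epsilon` | 1e-3 | MILP | meaningful growth ≫ solver tolerance |
| gap-fill `big_m` | 1000 | MILP | matches the default bound |
| tie-break budget | C(n,k) ≤ 2000 | gap-fill | bounded deterministic tie-break |
| DNF cap | 1024 terms | GPR | bound exponential expansion |
| essentiality threshold | 1/3 (+1e-6 slack) | deletions | severe-defect convention |
| ΔG band | ±30 kJ/mol, inclusive | reversibility | clear-irreversibility margin |
| calibration | bisection, 60 iters, rel 1e-4 | energetics | monotone branch, ~2^-60 bracket |
| FSEOF | 10 steps to 0.9·vmax | scan | stay strictly feasible |
| LP/MILP solver | scipy HiGHS | throughout | deterministic, no external deps |

## 13. Limitations

* Single-compartment toy scope; no charge/formula balancing or mass-balance
  auditing of arbitrary imported models beyond structural validation.
* SBML support covers the FBC constraint-based subset only; reaction kinds
  and any annotations are not round-tripped.
* The closed-form growth law holds only on the ATP-limited branch (section
  6); below the kink the fixed-flux NGAM forces wasteful ATP disposal and
  growth–GAEC monotonicity inverts.
* Gap-fill optimality is only oracle-verified up to 12 candidates;
  larger instances rely on the MILP (exact in principle) with a greedy
  fallback if the MILP solver fails.
* Analyses of published genome-scale models require their SBML files to be
  supplied locally (`scripts/salb_integration.py`); no such claims are made
  by the test suite.
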