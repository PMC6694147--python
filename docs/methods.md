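# Methods

## Scope and model

All four prediction methods operate on one data model: a stoichiometric
network with flux bounds (mmol·gDW⁻¹·h⁻¹; the biomass reaction in h⁻¹),
boolean gene–protein–reaction (GPR) rules, a single biomass objective, and a
growth medium expressed as uptake magnitudes.  Exchange reactions are oriented
`met →`, so uptake is a negative flux and a medium entry `u` sets `lb = −u`;
exchanges absent from the medium allow excretion only.  Gene knockouts are
encoded by evaluating each reaction's GPR with the deleted genes absent and
forcing unsatisfiable reactions to zero flux.  Spontaneous (rule-free)
reactions are never affected by knockouts and carry no enzyme cost.

Every optimisation problem in the package is a linear program, assembled as
sparse matrices and solved with scipy's HiGHS interface (primal/dual
feasibility tolerances 1e-9).  Infeasible knockout problems are reported as a
status, not an exception, and map to fitness 0 downstream — the lethal-
knockout semantics.

## The four methods

**FBA** maximises the biomass flux.  **pFBA** refixes the FBA optimum — the
biomass flux is constrained to `[z*(1−δ), z*]` with relative slack δ = 1e-9 —
and minimises `Σ|vᵢ|` through epigraph variables `tᵢ ≥ |vᵢ|`.  The two-stage
equality-fixing variant was chosen over fractional-optimum variants for
simplicity; the reported objective is the biomass flux, with the flux sum as
metadata.

**lMOMA** minimises the Manhattan distance `Σᵢ |vᵢ − vᵢʳᵉᶠ|` to the pFBA
wild-type reference over the knockout feasible space, again via epigraph
variables.  The pFBA anchor removes the arbitrariness of degenerate FBA
optima.  Fitness for lMOMA-based epistasis is normalised by the pFBA wild-type
biomass flux, and single-knockout fitnesses entering ε are lMOMA-derived as
well — lMOMA itself never solves a wild-type problem, so this is stated as an
explicit convention.  Ties among equidistant knockout solutions are resolved
by the solver's returned vertex; only the distance value is contractual.

**MOMENT / ccFBA** maximise growth under the enzyme-mass budget
`Σᵢ gᵢ·mᵢ ≤ C`, where `gᵢ` is the concentration variable of gene i's product.
Reaction capacities follow the GPR tree through auxiliary per-(reaction, node)
variables: an AND node's capacity is bounded by each child (complex limited by
its scarcest subunit, unit stoichiometry assumed), an OR node's by the sum of
its children (isoenzymes add).  Each member of an AND complex is costed at its
own molar mass in the budget; no complex-level mass aggregation is attempted.
A gated reaction's flux obeys `v ≤ k_cat · (root capacity)`; reversible gated
reactions are split into two non-negative directional fluxes sharing one
enzyme pool, each direction costed at its own k_cat when direction-specific
values are supplied and at the common value otherwise.  Medium uptake bounds
are opened (lb = −10⁶) in crowding mode — the budget replaces the
nutrient-uptake constraint — while uptakes closed by the medium stay closed;
this behaviour is configurable (`open_uptakes`).

The only difference between the two crowding methods is multifunctional-enzyme
accounting.  MOMENT lets `gᵢ` serve every reaction the gene gates
simultaneously.  ccFBA introduces per-(gene, reaction) usage variables
`uᵢⱼ ≥ 0` with `Σⱼ uᵢⱼ ≤ gᵢ`, and GPR leaves consume `uᵢⱼ` instead of `gᵢ`.
This makes ccFBA's feasible set a subset of MOMENT's, so its optimum can never
be larger; the two coincide exactly when no gene gates more than one reaction.
A gene appearing at several leaves of one reaction's GPR tree shares a single
`uᵢⱼ` for that reaction.  How a multifunctional gene inside an AND complex
that also acts alone elsewhere should be costed is genuinely underdetermined;
the per-(gene, reaction) splitting rule is one consistent reading, and the
invariants (budget-invariance of ε, ccFBA ≤ MOMENT) are the contract the
implementation is tested against.

Because the optimum of either crowding LP is linear in C, the budget cancels
from knockout/wild-type growth ratios: epistasis predictions are invariant to
C's numeric value.  The shipped default is C = 0.27 g·gDW⁻¹ with missing
turnover numbers imputed at the median of known values, k_cat,med = 11.5 h⁻¹
(the standard yeast parameterisation); both are plain parameters.

## Pipeline conventions

Fitness is `W = v / v_WT` with the wild type of the *same* method.  Scores
with `|ε| < 1e-9` are snapped to zero before classification so that solver
jitter cannot generate calls at the 1e-4 cutoff (configurable).  The
classification boundaries `ε = ±1e-4` are inclusive; the synthetic-lethality
cutoffs (`ε < −0.08`, `f < 0.2`) are strict.  Fitness values are not clipped
to [0, 1]; a warning is logged if a single-knockout fitness exceeds 1 + 1e-6,
since clipping would mask formulation bugs.  Pairs are unordered, self-pairs
excluded, outputs in lexicographic pair order, and single-knockout solutions
are memoised per method on a reusable problem instance (for crowding, only
gene-variable bounds are toggled between genotypes).

The analysable gene set excludes genes the model deems essential
(single-knockout FBA fitness < 1e-3) or blocked (no gated reaction can carry
flux beyond 1e-9 anywhere in the wild-type feasible region, assessed by flux
variability with the objective unconstrained).  Neither threshold has a
canonical published value; both are exposed as parameters, and genome-scale
pair counts will shift with them.

Two false-positive-rate conventions circulate for interaction screens: the
textbook `FP / (universe negatives)` and the "fraction of predictions not
confirmed" reading, which equals 1 − precision.  Both are computed and
labelled (`fpr_standard`, `fpr_paper`-style) so the ambiguity never silently
picks a side.  The default cutoff grid for sweeps is logarithmic from 1e-6 to
1e-1.  Experimental classes are taken from the input table as-is and never
re-thresholded.

## Synthetic data

The parallel-isoenzyme motif (several same-yield routes, gene-gated, with
cost-free uptake/biomass steps) has closed-form crowding solutions: growth is
`max k · C/m` over available isoforms, so with kcats (10, 10, 1) the fast pair
has W₁ = W₂ = 1, W₁₂ = 0.1, ε = −0.9, while FBA sees ε = 0 everywhere.

In the converging-pathway motif, each precursor has a fast gene-gated route
and an *inefficient backup modelled as a spontaneous reaction with a small
flux capacity* — the limiting-capacity idealisation of a costly bypass, made
enzyme-cost-exempt.  This choice makes the alleviating interaction exact
rather than approximate: the double knockout runs both branches on their
backups at zero enzyme cost, so `W₁₂ = min(W₁, W₂)` holds to solver precision
and `ε = min(W₁, W₂) − W₁·W₂ > 0`.  If the backups were instead gene-gated
with a slow k_cat, budget re-allocation in the double knockout would make
W₁₂ strictly smaller than min(W₁, W₂); the sign of ε survives but the exact
min-rule does not.  Both motifs are also shipped as static tabular files
(`tests/fixtures/`) so failures are inspectable without running generators.

Random toy models consist of a linear backbone (guaranteeing viability by
construction) with 1–3 parallel gated reactions per step, occasional two-gene
AND complexes, gene re-use across steps with probability `p_reuse` (the source
of multifunctionality), and occasional gated dead-end reactions (blocked by
construction).  kcats are log-uniform in [1, 100] h⁻¹, molar masses uniform in
[0.5, 2] g·mmol⁻¹ — spanning the two orders of magnitude of kinetic
heterogeneity that make cost effects visible at toy scale.  All generators use
one explicit numpy Generator seeded per call; no global random state.

The observed-call generator emulates only the statistical *shape* of a
high-confidence screen: mostly-zero scores, sparse signed interactions,
Bernoulli false-negative dropout at rate `fn_rate`, additive Gaussian score
jitter, and classes re-derived from the perturbed score.  It does not model
batch structure, correlated errors, false positives from array artefacts, or
fitness-dependent measurement noise — so closed-loop tests demonstrate the
correctness of the pipeline's bookkeeping, not robustness to realistic SGA
error modes.

## Problem sizes and numerics

Tests and the acceptance script run on networks of ≤ ~20 reactions and ≤ ~15
genes, sized so that the brute-force FBA oracle (exhaustive vertex enumeration
of the flux polytope, exponential in `n − rank(S)`) remains exact and the full
suite completes in well under a minute.  Vertex enumeration selects
`n − rank(S)` active finite bounds per candidate basis, solves the square
system, and keeps solutions feasible to 1e-9 relative tolerance; LP-vs-oracle
agreement is asserted at 1e-8.  Equality comparisons in tests use 1e-6 unless
a closed form justifies tighter.  Budget-invariance of ε is asserted at 1e-6
across C ∈ {0.05, 0.27, 1.0} over seeded random models.

## Known limitations

* Quadratic (Euclidean) MOMA, ROOM, loopless FBA and integer GPR encodings
  are out of scope.
* Crowding kinetics ignore metabolite concentrations (`[E] = v/k_cat` with a
  constant effective rate), translation machinery, and any proteome sectors
  beyond the single metabolic budget.
* Degenerate LP optima mean flux vectors (as opposed to objective values and
  distances) are solver-dependent; tests assert properties, never specific
  vertices.
* The genome-scale workflow (`examples/05`) is provided but unexercised by
  the test suite: it requires externally downloaded model and parameter
  files and hours of LP solves.
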