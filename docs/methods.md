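# Methods

## Model and problem statement

A genome-scale metabolic model is a stoichiometric matrix *S*, flux bounds
`lb ≤ v ≤ ub` (mmol·gDW⁻¹·h⁻¹; a negative lower bound encodes reversibility,
reactions are never split), gene–protein–reaction (GPR) boolean rules, and a
biomass objective.  Flux balance analysis (FBA) maximizes the objective
subject to `S·v = 0` and the bounds; flux variability analysis (FVA) reports
each reaction's attainable flux interval while the objective is held at a
fraction of its optimum.  Exchange fluxes follow the convention negative =
uptake, positive = secretion; applying a medium sets `lb = −(max uptake)` on
the listed exchanges and closes uptake (lb = 0) on all others, leaving
secretion open — minimal-medium semantics.

A knockout strategy is a set *D* of reactions forced to `lb = ub = 0`.  *D*
qualifies as a solution when the knockout model still grows at
`μ(D) ≥ c·μ_WT` (growth floor, `c = 0.01`) and the product exchange flux,
evaluated on the optimal-growth face, reaches the production threshold
`Th = f·V_chemical` with `f = 0.05`, where `V_chemical` is the wild-type
maximum theoretical production rate.  Two qualification modes exist:
`rate_max` uses the maximum of the product range at the optimum (production is
*possible* at maximal growth), `rate_grnt` its minimum (production is
*guaranteed* there).  Since the minimum never exceeds the maximum, every
guaranteed-rate solution is also a max-rate solution; the suite asserts this
inclusion level by level.

## Traversal and its completeness argument

Subsets of the removable candidate set are enumerated as a tree walked
depth-first.  For each node the **target space** is computed: the removable
reactions, minus those already deleted or owned by an earlier sibling branch,
that can carry nonzero flux at the node's growth optimum.  The default rule
(`fva_support`) asks fixed-optimum FVA whether `maxFlux > 10⁻⁶` or
`minFlux < −10⁻⁶`; the alternative (`fba_support`) keeps reactions with
nonzero flux in the single FBA vertex the solver happens to return.

The completeness argument for `fva_support` is: if reaction *r* is zero in
*every* optimal flux state of node *X*, then all optima of *X* remain optima
of *X ∪ {r}* and vice versa, so the two strains have identical growth and
identical product ranges at the optimum — `X ∪ {r}` qualifies exactly when
*X* does and is therefore never a *minimal* solution (when `X = ∅` it is a
vacuous intervention equivalent to the wild type).  Excluding *r* from the
subtree loses nothing.  `fba_support` lacks this guarantee: under a degenerate
optimum (the canonical toy's R3/R4 split) the returned vertex may carry zero
flux through the one reaction whose deletion is the solution.  It is retained
because it solves exactly one LP per node — on genome-scale models it is the
configuration whose LP count equals the node count — and the tests document
the rule difference explicitly.

Pruning uses two monotone criteria: an infeasible knockout LP, or growth
below the floor, can only get worse as knockouts accumulate, so the subtree is
skipped.  (Infeasibility alone is the textbook prune; the growth floor is an
extension justified by the same monotonicity, since `μ` is non-increasing
along any root-to-leaf path.)  Duplicate elimination uses per-branch checked
sets: children expand in lexicographic reaction-id order, and once a child's
subtree is exhausted its reaction is excluded from all deeper levels of its
later siblings.  Qualifying nodes are recorded *and* expanded, because deeper
supersets can qualify independently; a final minimality filter drops any
recorded set with a recorded proper subset.  The exhaustive oracle
(`knockscan.oracle`) shares the qualification code path, so oracle/search
disagreements isolate traversal bugs rather than threshold drift.

In gene mode the candidate set keeps only gene-associated reactions, each
strategy is realized by a minimal gene-deletion set (fewest genes, ties broken
lexicographically — the selection rule is a package choice), the *co-knocked*
reactions silenced by those genes are zeroed together with the targets, and
strategies whose effective reaction sets coincide are canonicalized to one
record.  Minimal disabling gene sets are computed by structural recursion on
the GPR tree (AND: union of child families; OR: pairwise unions) with superset
elimination at every step; pathological rules with huge families fall back to
a greedy smallest-set choice beyond 50 000 combinations.

## Preprocessing

Blocked reactions are those with FVA range [0, 0] at objective fraction 0
(tolerance 10⁻⁶).  Dead-end metabolites are found structurally — species that
cannot both be produced and consumed given bounds and reversibility — and the
removal cascades to a fixed point, since stranding a reaction can expose new
dead ends.  Both removals are flux-neutral, so the reduced model keeps the
wild-type optimum (asserted in the suite).  Candidates then exclude boundary
reactions (exchanges, demands, sinks — the medium is an experimental control,
not a genetic intervention), the objective reaction, user-listed ids, and
essential reactions, defined against the same 1% growth floor used for
solution qualification rather than strict lethality, so that every remaining
single knockout is guaranteed viable.

## Strain metrics

* **Production envelope**: minimum/maximum product flux on a uniform growth
  grid from 0 to `μ_max` (default 40 points, 2 LPs per point, biomass pinned
  to the grid value within a 10⁻⁹ relative slack).
* **Yield** `Y = v_P / v_S` with `v_S` the positive substrate-uptake
  magnitude; **SSP** defaults to `μ·v_P` (the tabulated convention of the
  strain-comparison literature this package targets), with `μ·Y` available via
  `ssp_definition="yield"`.
* **SoGC** `= Y² / slope`, slope taken from the final linear segment of the
  envelope's lower edge, detected by walking breakpoints backwards from
  `μ_max` with relative slope tolerance 10⁻⁴; a two-point finite difference at
  `μ_max` is selectable.  A flat or declining lower edge means production is
  not growth-enforced: SoGC is reported as 0 with a flag rather than a
  division error.
* **CO₂ exchange**: with growth pinned at its optimum and the product at its
  maximum there, the flux state is generally degenerate, so the CO₂ exchange
  is reported as an FVA range plus midpoint instead of a single arbitrary
  vertex value.
* **Linear MOMA** minimizes `Σ_r |v_r − v_r^wild|` over the knockout model via
  one split auxiliary variable per reaction.  The distance runs over *all*
  reactions, exchanges included — the standard L1 form, and the one COBRApy's
  linear MOMA also solves (used as an independent cross-check in the tests,
  alongside a scipy.linprog oracle).  The wild-type reference is the
  deterministic FBA vertex of the base model under the same medium unless the
  caller supplies one.

## Numerical choices

GLPK (COBRApy's default backend) is used with its deterministic default
pivoting, so repeated runs on one machine return the same optimal vertex; this
is documented as a contract, not a cross-version guarantee.  Fluxes with
magnitude ≤ 10⁻⁶ count as zero everywhere (feasibility-tolerance scale).
"Objective pinned at its optimum" is implemented as
`objective ≥ (1 − 10⁻⁹)·optimum` to avoid empty feasible sets under
floating-point ties.  Threshold comparisons use `≥` with absolute tolerance
10⁻⁶.  LP accounting distinguishes node-level FBAs (one per constructed tree
node, root included) from variability sub-problems, which are tallied
separately.

## Synthetic models: what they emulate and what they do not

The generator builds a substrate-uptake → branched-pathway motif with a
cofactor cycle: growth consumes the reduced cofactor, and only the product
branch or one of `n_branches` byproduct branches re-reduces it.  Byproduct
capacities are drawn uniformly from [2.5, 4.0] mmol·gDW⁻¹·h⁻¹ against a total
cofactor demand of 5 at the growth optimum and a substrate uptake of 10 —
chosen so that no single open branch can absorb the full demand but any two
can, which makes the qualifying cardinality depend on the branch count (pairs
for three branches, singles for two, triples for four) and gives the oracle
non-trivial minimality structure.  GPR styles cover one-to-one rules, a shared
gene across two branches (guaranteeing a co-knocked pair), and isozyme pairs.
Draws are reproducible from the spec seed.

These toys exercise correctness, not scale: every internal reaction can carry
flux at the optimum, so target spaces barely shrink and the traversal's node
count approaches the exhaustive subset count (the acceptance script reports
this ratio honestly at ~100% for k ≤ 3 on toys).  The pruning pay-off —
orders-of-magnitude fewer nodes than subsets — only materializes on
genome-scale networks, where most candidate reactions are idle at any given
optimum.  Passing the toy suite demonstrates completeness and qualification
semantics, not performance, and says nothing about numerical behaviour on
poorly scaled industrial models.

## Problem sizes used by the shipped checks

The acceptance script and suite run the canonical 8-reaction toy plus 20
seeded variants (9–15 reactions) to knockout depth k = 3, with the exhaustive
oracle bounded at 200 000 subsets.  Published-number checks on the iJR904
E. coli GEM (anaerobic glucose minimal medium, succinate) are included in the
suite but require the model file, which is not redistributable here; they load
`scratch/iJR904.json` or attempt one short download and otherwise fail with a
diagnostic.  The enumeration-count check uses the `fba_support` rule, matching
the one-LP-per-node accounting under which those counts were originally
obtained.

## Known limitations

* Completeness is proven relative to the target-space argument above; a
  wild-type-equivalent single knockout (a reaction carrying zero flux in every
  wild-type optimum that is nonetheless unblocked) is deliberately not
  reported, as it changes nothing about the strain.
* Parallel execution is accepted in the configuration but runs sequentially;
  the determinism contract (byte-identical sorted solution tables) is the
  binding requirement, not speed.
* Only linear MOMA is provided (no quadratic variant, no parsimonious or
  loopless FBA).
* The preprocessing exclusion rules are configurable precisely because
  essentiality cutoffs and candidate filters vary between studies; the suite's
  iJR904 calibration check states which configuration (gene-mode filtering on)
  it compares against the published candidate count.
* SSP's tabulated convention `μ·v_P` carries units mmol·gDW⁻¹·h⁻²; the
  literature's `μ·Y` (h⁻¹) is available behind the flag but the numbers
  reported by default follow the tabulated convention.
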