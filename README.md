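# knockscan

Exhaustive — yet pruned — enumeration of **all** reaction (or gene) knockout
strategies up to a chosen cardinality *k* that couple overproduction of a
target metabolite to growth in a genome-scale metabolic model (GEM), plus the
metrics used to rank the resulting strains.

## Who this is for

Metabolic engineers and systems biologists doing *in silico* strain design.
Bilevel optimizers (OptKnock-style) return one optimal strategy; minimal-cut-set
enumerators return many but filter by preset thresholds and can miss or
non-minimally report strategies.  When the design criterion is nonlinear
(e.g. strength of growth coupling) or practical (gene loci, CO₂ fixation,
byproduct toxicity), what you actually want is the *complete* list of
qualifying knockout sets, ranked afterwards by whatever index you care about.

## The method

A GEM is analyzed under flux balance analysis: maximize biomass flux subject to
steady state `S·v = 0` and bounds `lb ≤ v ≤ ub`.  Knocking out reaction *r*
sets `lb_r = ub_r = 0`.  A knockout set *D* **qualifies** when

* growth survives: `μ(D) ≥ 0.01·μ_WT`, and
* the product exchange flux at the growth optimum reaches
  `Th = 0.05·V_chemical` (5% of the maximum theoretical production rate of the
  wild type) — with its **maximum** over the optimal face in `rate_max` mode,
  or its **minimum** (guaranteed production) in `rate_grnt` mode.

All subsets of size ≤ k of the *removable* candidate set are organized as a
tree (root = wild type, level L = L deletions) and walked depth-first with
three prunes that provably lose no minimal solution:

1. **Target spaces** — a child reaction is only tried if it can carry flux at
   the parent's growth optimum (fixed-optimum FVA); deleting an
   always-zero-at-optimum reaction yields a strain equivalent to its parent.
2. **Monotone pruning** — an infeasible node, or one below the growth floor,
   drops its whole subtree (adding knockouts never raises the optimum).
3. **Checked sets** — lexicographic expansion with per-branch exclusion, so
   each unordered set is visited at most once.

Preprocessing first removes blocked reactions and dead-end metabolites
(flux-neutral), then excludes exchanges, the objective, essential reactions
(single knockout drops growth below the floor), user exclusions, and — in gene
mode — reactions with no gene association.  Gene mode additionally translates
each strategy into a minimal gene-deletion set and zeroes the *co-knocked*
reactions silenced by the same genes.

Enumerated strategies are ranked by production envelope, yield
`Y_P/S = v_P / v_S`, substrate-specific productivity `SSP = μ·v_P`, strength of
growth coupling `SoGC = Y²_P/S / slope` (slope of the final linear segment of
the envelope's lower edge), CO₂ exchange range, and linear MOMA (L1-closest
post-knockout flux state to a wild-type distribution).

## Worked example

```python
import knockscan as ks

model = ks.make_toy1()                      # hand-solvable cofactor-coupling toy
pre = ks.compute_removable_set(model)
cfg = ks.TraversalConfig(target_level=2, mode="rate_grnt")
res = ks.traverse_tree(model, pre.removable, "EX_P", cfg)

print("gr_WT       =", res.thresholds.gr_wt)          # 5.0
print("V_chemical  =", res.thresholds.v_chemical)     # 5.0
print("Th_chemical =", res.thresholds.th_chemical)    # 0.25
for s in res.solutions:
    print(s.reactions, s.growth, s.product_min, s.product_max)
# ('R4',) 5.0 5.0 5.0
```

The toy takes up 10 units of substrate; half feeds growth, half must
re-reduce a cofactor through either the product branch R3 or the byproduct
branch R4.  Wild-type growth is 5.0 and the production threshold is
0.25 (= 5% of the theoretical maximum 5.0).  The single strategy `{R4}` closes
the byproduct branch, so cofactor regeneration — and hence product secretion at
5.0 mmol·gDW⁻¹·h⁻¹ — becomes mandatory at the unchanged growth optimum; its
envelope lower edge has slope 1, yield 0.5, SoGC 0.25.

The same run from the shell:

```bash
knockscan enumerate --model toy1.json --product EX_P --max-k 2 --mode grnt --out run/
knockscan metrics --model toy1.json --product EX_P --substrate EX_A \
    --solutions run/solutions.tsv --out run/metrics.tsv
```

See `examples/` for narrative scripts (enumeration, ranking, gene-level
knockouts with co-knocked reactions).

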