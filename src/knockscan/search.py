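"""Depth-first enumeration of all growth-coupled knockout strategies.

The search walks a tree whose nodes are unordered sets of deleted reactions:
the root is the wild type, a node at level L deletes L reactions, and leaves
sit at the requested cardinality k.  Three ideas keep the walk tractable
without sacrificing completeness:

* **Target spaces.**  A child deletion is only worth trying if the candidate
  reaction can carry flux at the parent's growth optimum — deleting a reaction
  that is zero in *every* optimal flux state changes neither the optimum nor
  the product range there, so any solution it appears in is equivalent to a
  smaller one.  The default ``fva_support`` rule collects all removable
  reactions whose fixed-optimum FVA interval strays from zero.  The cheaper
  ``fba_support`` rule keeps only reactions with nonzero flux in the single
  FBA vertex returned by the solver; it needs no variability LPs but a
  degenerate optimum can hide true solutions behind the solver's arbitrary
  vertex choice, so it is opt-in.

* **Pruning.**  Both knockout infeasibility and the growth floor
  (1% of wild-type growth by default) are monotone under added knockouts, so
  a node failing either test can drop its whole subtree.

* **Checked sets.**  Children are expanded in lexicographic order and a
  reaction whose subtree has been fully explored is excluded from the
  subtrees of its later siblings, so each unordered set is visited at most
  once.

Every node at level >= 1 that survives pruning is tested for solution
qualification: its product-exchange flux range at the pinned growth optimum
must reach the production threshold Th (5% of the maximum theoretical rate by
default) — with the maximum of the range in ``rate_max`` mode, or with the
minimum (guaranteed production) in ``rate_grnt`` mode.  A qualifying node's
subtree is still expanded, since deeper sets can qualify in their own right.
Because a qualifying set may contain a smaller qualifying set (a solution plus
a merely flux-capable reaction), a minimality post-filter keeps only sets with
no qualifying proper subset.

One FBA is solved per constructed node, so ``SearchResult.lp_count`` equals
``SearchResult.node_count``; variability LPs are tallied separately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Optional, Set, Tuple

import numpy as np
from cobra import Model

from .errors import ConfigurationError, InfeasibleModelError
from .genes import GeneDeletionPlan, plan_gene_deletions
from .lp import (
    LPCounter,
    OPTIMUM_SLACK,
    ZERO_TOL,
    FluxResult,
    product_rates_at_optimal_growth,
    solve_fba,
)

#: absolute tolerance on threshold comparisons
QUALIFY_TOL = 1e-6

#: hard cap on the knockout cardinality accepted from configuration
MAX_TARGET_LEVEL = 10


@dataclass(frozen=True)
class TraversalConfig:
    """Knobs of one enumeration run."""

    target_level: int = 2
    biomass_cutoff_fraction: float = 0.01
    product_threshold_fraction: float = 0.05
    mode: str = "rate_grnt"  # or "rate_max"
    target_space_rule: str = "fva_support"  # or "fba_support"
    gene_mode: bool = False
    pinned: FrozenSet[str] = frozenset()
    worker_count: int = 1

    def __post_init__(self):
        if not 1 <= self.target_level <= MAX_TARGET_LEVEL:
            raise ConfigurationError(
                f"target_level must be in [1, {MAX_TARGET_LEVEL}], got {self.target_level}"
            )
        if not 0 < self.biomass_cutoff_fraction < 1:
            raise ConfigurationError("biomass_cutoff_fraction must lie in (0, 1)")
        if not 0 < self.product_threshold_fraction < 1:
            raise ConfigurationError("product_threshold_fraction must lie in (0, 1)")
        if self.mode not in ("rate_max", "rate_grnt"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if self.target_space_rule not in ("fva_support", "fba_support"):
            raise ConfigurationError(f"unknown target_space_rule {self.target_space_rule!r}")


@dataclass(frozen=True)
class Thresholds:
    """Wild-type anchors every qualification decision refers to."""

    gr_wt: float
    v_chemical: float
    th_chemical: float
    biomass_floor: float


@dataclass
class Node:
    """One vertex of the traversal tree."""

    level: int
    deleted_rxns: FrozenSet[str]
    flux_dist: Optional[FluxResult] = None
    target_space: Optional[FrozenSet[str]] = None


@dataclass(frozen=True)
class SolutionRecord:
    """A qualified knockout strategy."""

    reactions: Tuple[str, ...]
    level: int
    growth: float
    product_min: float
    product_max: float
    qualifying_mode: str  # rate_max | rate_grnt | both
    genes: Tuple[str, ...] = ()
    co_knocked: Tuple[str, ...] = ()

    @property
    def key(self) -> FrozenSet[str]:
        return frozenset(self.reactions)


@dataclass
class SearchResult:
    """Minimal solutions plus the raw qualified sets and LP/node accounting."""

    solutions: List[SolutionRecord]
    raw_solutions: Dict[FrozenSet[str], SolutionRecord]
    node_count: int
    lp_count: int
    fva_lp_count: int
    thresholds: Thresholds
    config: TraversalConfig


def compute_thresholds(
    model: Model,
    product_exchange_id: str,
    config: TraversalConfig,
    counter: Optional[LPCounter] = None,
) -> Thresholds:
    """Wild-type growth, maximum theoretical production, and both cutoffs.

    The two setup solves are not node-level FBAs; when a counter is given they
    are tallied with the variability LPs.
    """
    base = solve_fba(model)
    vres = solve_fba(model, objective_id=product_exchange_id)
    if counter is not None:
        counter.fva_lps += 2
    if not base.ok or base.objective_value is None:
        raise InfeasibleModelError("base model infeasible; thresholds undefined")
    if not vres.ok or vres.objective_value is None:
        raise InfeasibleModelError("product maximization infeasible")
    gr_wt = base.objective_value
    v_chem = vres.objective_value
    if v_chem <= ZERO_TOL:
        warnings.warn(
            f"maximum theoretical rate of {product_exchange_id} is zero; "
            "the production threshold degenerates to 0 and every growth-viable "
            "node will qualify",
            stacklevel=2,
        )
    return Thresholds(
        gr_wt=gr_wt,
        v_chemical=v_chem,
        th_chemical=config.product_threshold_fraction * v_chem,
        biomass_floor=config.biomass_cutoff_fraction * gr_wt,
    )


def identify_target_space(
    model: Model,
    deleted_rxns: FrozenSet[str],
    removable: FrozenSet[str],
    rule: str = "fva_support",
    counter: Optional[LPCounter] = None,
    excluded: FrozenSet[str] = frozenset(),
    flux_dist: Optional[FluxResult] = None,
) -> Tuple[FrozenSet[str], Optional[FluxResult]]:
    """Removable reactions that can still matter below the given node.

    ``model`` must already have ``deleted_rxns`` knocked out.  Returns the
    empty set when the node is infeasible (the caller prunes; nothing is
    raised out of the traversal).  ``excluded`` is subtracted up front so no
    variability LP is wasted on reactions another branch already owns; a
    pre-solved ``flux_dist`` for this node avoids a redundant FBA.
    """
    candidates = sorted(removable - deleted_rxns - excluded)
    if flux_dist is None:
        flux_dist = solve_fba(model, counter=counter)
    if not flux_dist.ok or flux_dist.objective_value is None:
        return frozenset(), flux_dist

    if rule == "fba_support":
        if flux_dist.fluxes is None:
            flux_dist = solve_fba(model, counter=counter)
            if not flux_dist.ok or flux_dist.fluxes is None:
                return frozenset(), flux_dist
        fluxes = flux_dist.fluxes
        return frozenset(r for r in candidates if abs(fluxes[r]) > ZERO_TOL), flux_dist

    if rule != "fva_support":
        raise ConfigurationError(f"unknown target_space_rule {rule!r}")
    opt = flux_dist.objective_value
    supported: Set[str] = set()
    with model:
        obj_rxn = [r for r in model.reactions if r.objective_coefficient][0]
        bound = opt - OPTIMUM_SLACK * max(1.0, abs(opt))
        if bound > obj_rxn.lower_bound:
            obj_rxn.lower_bound = bound
        for rid in candidates:
            rxn = model.reactions.get_by_id(rid)
            model.objective = rxn
            model.objective_direction = "max"
            hi = model.slim_optimize(error_value=0.0)
            if counter is not None:
                counter.fva_lps += 1
            if hi > ZERO_TOL:
                supported.add(rid)
                continue
            model.objective_direction = "min"
            lo = model.slim_optimize(error_value=0.0)
            if counter is not None:
                counter.fva_lps += 1
            if lo < -ZERO_TOL:
                supported.add(rid)
    return frozenset(supported), flux_dist


def construct_subtree(node: Node, checked: Iterable[str] = ()) -> List[Node]:
    """Children of a node: one per target-space reaction not yet checked,
    ordered lexicographically by reaction id."""
    if node.target_space is None:
        raise ValueError("target_space must be computed before expanding a node")
    checked = set(checked)
    return [
        Node(level=node.level + 1, deleted_rxns=node.deleted_rxns | {rid})
        for rid in sorted(node.target_space - checked)
    ]


def qualify_solution(
    model: Model,
    product_exchange_id: str,
    deleted_rxns: FrozenSet[str],
    thresholds: Thresholds,
    mode: str,
    counter: Optional[LPCounter] = None,
    growth: Optional[float] = None,
    genes: Tuple[str, ...] = (),
    co_knocked: Tuple[str, ...] = (),
) -> Optional[SolutionRecord]:
    """Test one knockout set against the production threshold.

    ``model`` must have the effective knockout applied and be feasible with
    growth at or above the floor.  Qualification is on the product-flux range
    at the pinned growth optimum: the maximum must reach Th in ``rate_max``
    mode, the minimum in ``rate_grnt`` mode (both with absolute tolerance
    1e-6).  Returns a record when the set qualifies, else ``None``.
    """
    rates = product_rates_at_optimal_growth(
        model, product_exchange_id, counter=counter, growth=growth
    )
    ok_max = rates.product_max >= thresholds.th_chemical - QUALIFY_TOL
    ok_grnt = rates.product_min >= thresholds.th_chemical - QUALIFY_TOL
    if not (ok_grnt if mode == "rate_grnt" else ok_max):
        return None
    qmode = "both" if (ok_max and ok_grnt) else ("rate_grnt" if ok_grnt else "rate_max")
    return SolutionRecord(
        reactions=tuple(sorted(deleted_rxns)),
        level=len(deleted_rxns),
        growth=rates.growth,
        product_min=rates.product_min,
        product_max=rates.product_max,
        qualifying_mode=qmode,
        genes=genes,
        co_knocked=co_knocked,
    )


def minimal_solutions(raw: Dict[FrozenSet[str], SolutionRecord]) -> List[SolutionRecord]:
    """Keep only qualified sets with no qualified proper subset."""
    keys = sorted(raw, key=lambda s: (len(s), tuple(sorted(s))))
    minimal: List[FrozenSet[str]] = []
    for key in keys:
        if not any(m < key for m in minimal):
            minimal.append(key)
    return [raw[k] for k in minimal]


def traverse_tree(
    model: Model,
    removable: Iterable[str],
    product_exchange_id: str,
    config: TraversalConfig,
    counter: Optional[LPCounter] = None,
) -> SearchResult:
    """Enumerate all qualifying knockout sets up to ``config.target_level``.

    ``model`` must have its medium applied.  Pinned reactions (a user
    heuristic for deep searches) are knocked out up front and do not count
    toward the cardinality.  Execution is sequential regardless of
    ``worker_count``; the contract is that any execution order yields the same
    sorted solution table, and lexicographic child expansion makes the
    sequential order canonical.
    """
    counter = counter if counter is not None else LPCounter()
    removable = frozenset(removable) - config.pinned
    if product_exchange_id not in model.reactions:
        raise ConfigurationError(f"unknown product exchange {product_exchange_id!r}")
    for rid in config.pinned:
        if rid not in model.reactions:
            raise ConfigurationError(f"pinned reaction {rid!r} not in model")

    gene_plans: Dict[FrozenSet[str], GeneDeletionPlan] = {}

    def effective(deleted: FrozenSet[str]) -> Tuple[FrozenSet[str], Tuple[str, ...], Tuple[str, ...]]:
        if not config.gene_mode:
            return deleted, (), ()
        if deleted not in gene_plans:
            gene_plans[deleted] = plan_gene_deletions(deleted, model)
        plan = gene_plans[deleted]
        return (
            plan.effective_reactions,
            tuple(sorted(plan.deleted_genes)),
            tuple(sorted(plan.co_knocked)),
        )

    state = {"node_count": 0}
    raw: Dict[FrozenSet[str], SolutionRecord] = {}
    seen_effective: Set[FrozenSet[str]] = set()
    needs_fluxes = config.target_space_rule == "fba_support"

    with model:
        for rid in config.pinned:
            model.reactions.get_by_id(rid).bounds = (0.0, 0.0)

        thresholds = compute_thresholds(model, product_exchange_id, config, counter=counter)
        if thresholds.gr_wt < ZERO_TOL:
            raise InfeasibleModelError("wild-type growth is zero under this medium")

        def expand(parent: Node, excluded: FrozenSet[str]) -> None:
            """Create and visit the children of ``parent`` (already applied)."""
            target_space, flux_dist = identify_target_space(
                model,
                parent.deleted_rxns,
                removable,
                rule=config.target_space_rule,
                counter=counter,
                excluded=excluded,
                flux_dist=parent.flux_dist,
            )
            parent.target_space = target_space
            parent.flux_dist = flux_dist
            checked: Set[str] = set()
            for child in construct_subtree(parent, checked=()):
                (rid,) = child.deleted_rxns - parent.deleted_rxns
                if rid in checked:  # pragma: no cover - children precomputed
                    continue
                state["node_count"] += 1
                eff, genes, co = effective(child.deleted_rxns)
                with model:
                    for r in eff - config.pinned:
                        model.reactions.get_by_id(r).bounds = (0.0, 0.0)
                    if needs_fluxes:
                        child.flux_dist = solve_fba(model, counter=counter)
                        growth = child.flux_dist.objective_value
                    else:
                        g = model.slim_optimize(error_value=float("nan"))
                        counter.node_lps += 1
                        growth = None if np.isnan(g) else float(g)
                        child.flux_dist = FluxResult(
                            "optimal" if growth is not None else "infeasible", growth, None
                        )
                    viable = growth is not None and growth >= thresholds.biomass_floor - ZERO_TOL
                    if viable:
                        if eff not in seen_effective:
                            seen_effective.add(eff)
                            rec = qualify_solution(
                                model,
                                product_exchange_id,
                                child.deleted_rxns,
                                thresholds,
                                config.mode,
                                counter=counter,
                                growth=growth,
                                genes=genes,
                                co_knocked=co,
                            )
                            if rec is not None:
                                raw[child.deleted_rxns] = rec
                        if child.level < config.target_level:
                            expand(child, frozenset(excluded | checked))
                checked.add(rid)

        root = Node(level=0, deleted_rxns=frozenset())
        state["node_count"] += 1
        expand(root, frozenset())  # root FBA solved inside identify_target_space

    sols = minimal_solutions(raw)
    return SearchResult(
        solutions=sols,
        raw_solutions=raw,
        node_count=state["node_count"],
        lp_count=counter.node_lps,
        fva_lp_count=counter.fva_lps,
        thresholds=thresholds,
        config=config,
    )
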