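"""Exhaustive enumeration oracle for completeness checks.

Tests every reaction subset of size 1..k with exactly the same qualification
rule as the tree search (shared code path, so a disagreement isolates a
traversal bug rather than threshold drift).  Intended for small candidate sets
only; the subset count is guarded by an explicit budget.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Optional

import numpy as np
from cobra import Model

from .errors import BudgetExceededError
from .genes import plan_gene_deletions
from .lp import LPCounter, ZERO_TOL
from .search import (
    SolutionRecord,
    TraversalConfig,
    compute_thresholds,
    minimal_solutions,
    qualify_solution,
)


@dataclass
class OracleResult:
    """Raw qualifying subsets, the minimal ones, and the LPs spent."""

    raw_solutions: Dict[FrozenSet[str], SolutionRecord]
    minimal: List[SolutionRecord]
    lp_count: int
    subsets_tested: int


def subset_count(n: int, k: int) -> int:
    """Number of subsets of size 1..k over n candidates."""
    return sum(math.comb(n, j) for j in range(1, k + 1))


def exhaustive_search(
    model: Model,
    removable: Iterable[str],
    product_exchange_id: str,
    config: TraversalConfig,
    budget: int = 200_000,
    counter: Optional[LPCounter] = None,
) -> OracleResult:
    """Qualify every subset of ``removable`` up to size ``config.target_level``.

    Subsets are visited in lexicographic order for reproducible failure
    reports.  Raises :class:`BudgetExceededError` when the subset count
    exceeds ``budget`` (choose a smaller k or candidate set).
    """
    counter = counter if counter is not None else LPCounter()
    removable = sorted(frozenset(removable) - config.pinned)
    k = config.target_level
    n_subsets = subset_count(len(removable), k)
    if n_subsets > budget:
        raise BudgetExceededError(
            f"{n_subsets} subsets exceed the oracle budget of {budget}; reduce k"
        )

    raw: Dict[FrozenSet[str], SolutionRecord] = {}
    tested = 0
    with model:
        for rid in config.pinned:
            model.reactions.get_by_id(rid).bounds = (0.0, 0.0)
        thresholds = compute_thresholds(model, product_exchange_id, config, counter=counter)
        for size in range(1, k + 1):
            for combo in itertools.combinations(removable, size):
                tested += 1
                deleted = frozenset(combo)
                if config.gene_mode:
                    eff = plan_gene_deletions(deleted, model).effective_reactions
                    genes_co = plan_gene_deletions(deleted, model)
                    genes = tuple(sorted(genes_co.deleted_genes))
                    co = tuple(sorted(genes_co.co_knocked))
                else:
                    eff, genes, co = deleted, (), ()
                with model:
                    for r in eff - config.pinned:
                        model.reactions.get_by_id(r).bounds = (0.0, 0.0)
                    growth = model.slim_optimize(error_value=float("nan"))
                    counter.node_lps += 1
                    if np.isnan(growth) or growth < thresholds.biomass_floor - ZERO_TOL:
                        continue
                    rec = qualify_solution(
                        model,
                        product_exchange_id,
                        deleted,
                        thresholds,
                        config.mode,
                        counter=counter,
                        growth=float(growth),
                        genes=genes,
                        co_knocked=co,
                    )
                    if rec is not None:
                        raw[deleted] = rec
    return OracleResult(
        raw_solutions=raw,
        minimal=minimal_solutions(raw),
        lp_count=counter.node_lps,
        subsets_tested=tested,
    )
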