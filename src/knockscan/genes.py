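"""Translating reaction knockouts into gene deletions and co-knockouts.

Deleting the genes that switch off a targeted reaction can silence further
reactions that depend on the same genes; those are the *co-knocked* reactions
and they are part of the real genetic intervention.  Gene-level searches
therefore zero the bounds of the whole effective set
``targets + co_knocked``, and two strategies whose effective sets coincide
are the same strain.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import FrozenSet, Iterable, List, Tuple

from cobra import Model

from .errors import BudgetExceededError, ConfigurationError
from .gpr import genes_disabling_reaction

#: maximum number of per-reaction minimal-set combinations examined exactly
_COMBINATION_BUDGET = 50_000


@dataclass(frozen=True)
class GeneDeletionPlan:
    """Gene deletions realizing a reaction strategy, plus side effects."""

    target_reactions: FrozenSet[str]
    deleted_genes: FrozenSet[str]
    co_knocked: FrozenSet[str]

    @property
    def effective_reactions(self) -> FrozenSet[str]:
        """Reactions actually forced to zero flux by the gene deletions."""
        return self.target_reactions | self.co_knocked


def _co_knocked(model: Model, deleted_genes: FrozenSet[str], targets: FrozenSet[str]) -> FrozenSet[str]:
    out = set()
    for rxn in model.reactions:
        if rxn.id in targets or rxn.gpr.body is None:
            continue
        if not rxn.gpr.eval(knockouts=deleted_genes):
            out.add(rxn.id)
    return frozenset(out)


def plan_gene_deletions(strategy: Iterable[str], model: Model) -> GeneDeletionPlan:
    """Choose a minimal gene-deletion set realizing a reaction strategy.

    Per reaction the minimal disabling gene sets are enumerated; across
    reactions the combination with the fewest genes in its union is chosen,
    ties broken lexicographically.  Reactions with an empty GPR cannot be
    deleted genetically and raise :class:`ConfigurationError`.
    """
    targets = frozenset(strategy)
    if not targets:
        return GeneDeletionPlan(frozenset(), frozenset(), frozenset())
    families: List[List[frozenset]] = []
    for rid in sorted(targets):
        if rid not in model.reactions:
            raise ConfigurationError(f"unknown reaction {rid!r} in strategy")
        fam = genes_disabling_reaction(model.reactions.get_by_id(rid))
        if not fam:
            raise ConfigurationError(
                f"reaction {rid!r} has no gene association and cannot be knocked out genetically"
            )
        families.append(fam)
    n_comb = 1
    for fam in families:
        n_comb *= len(fam)
    if n_comb > _COMBINATION_BUDGET:
        # greedy fallback: smallest (then lexicographic) set per reaction
        union: set = set()
        for fam in families:
            union |= min(fam, key=lambda s: (len(s), sorted(s)))
        genes = frozenset(union)
    else:
        best: Tuple[int, Tuple[str, ...]] | None = None
        genes = frozenset()
        for combo in itertools.product(*families):
            union = frozenset().union(*combo)
            key = (len(union), tuple(sorted(union)))
            if best is None or key < best:
                best = key
                genes = union
    return GeneDeletionPlan(targets, frozenset(genes), _co_knocked(model, frozenset(genes), targets))


def expand_with_co_knockouts(strategy: Iterable[str], model: Model) -> FrozenSet[str]:
    """The reaction set actually zeroed in the LP when deleting genes."""
    plan = plan_gene_deletions(strategy, model)
    return plan.effective_reactions
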