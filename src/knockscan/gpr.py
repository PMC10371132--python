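"""Gene-protein-reaction (GPR) rule evaluation and minimal disabling sets.

A GPR is a boolean expression over gene ids with AND/OR connectives: AND means
all subunits of a complex are required, OR means isozymes substitute for each
other.  Rules are parsed by COBRApy (:class:`cobra.core.gene.GPR`), which
accepts lowercase/uppercase connectives and parentheses; genes are opaque
strings.  An empty rule evaluates active (no known genetic dependency).

Beyond plain evaluation this module computes the *minimal disabling gene
sets* of a rule: the inclusion-minimal sets of genes whose joint deletion
makes the rule evaluate false.  For an AND node any disabling set of any
conjunct suffices; for an OR node every disjunct must be disabled, so the
families are combined by pairwise union.  Supersets are discarded at every
step, which keeps the families small for realistic rules.
"""

from __future__ import annotations

import ast
from typing import List, Sequence, Set, Union

from cobra import Reaction
from cobra.core.gene import GPR

GprLike = Union[str, GPR]


def parse_gpr(rule: GprLike) -> GPR:
    """Parse a rule string into a GPR (idempotent for GPR input)."""
    if isinstance(rule, GPR):
        return rule
    return GPR.from_string(rule)


def evaluate_gpr(gpr: GprLike, deleted_genes: Set[str] = frozenset()) -> bool:
    """Standard boolean semantics with deleted genes false; empty rule is active."""
    return bool(parse_gpr(gpr).eval(knockouts=deleted_genes))


def _minimalize(families: Sequence[frozenset]) -> List[frozenset]:
    """Drop any set that contains another set of the family."""
    uniq = sorted(set(families), key=lambda s: (len(s), sorted(s)))
    kept: List[frozenset] = []
    for s in uniq:
        if not any(k <= s for k in kept):
            kept.append(s)
    return kept


def _disabling(node) -> List[frozenset]:
    if isinstance(node, ast.Name):
        return [frozenset([node.id])]
    if isinstance(node, ast.BoolOp):
        child_families = [_disabling(v) for v in node.values]
        if isinstance(node.op, ast.And):
            merged: List[frozenset] = []
            for fam in child_families:
                merged.extend(fam)
            return _minimalize(merged)
        if isinstance(node.op, ast.Or):
            families = child_families[0]
            for fam in child_families[1:]:
                families = _minimalize([a | b for a in families for b in fam])
            return families
    raise ValueError(f"unsupported GPR node {ast.dump(node)}")


def minimal_disabling_gene_sets(gpr: GprLike) -> List[frozenset]:
    """Inclusion-minimal gene sets whose deletion inactivates the rule.

    An empty rule returns ``[]``: no gene deletion can switch it off, so the
    reaction is non-deletable at the gene level.  Results are sorted by size
    then lexicographically for reproducibility.
    """
    g = parse_gpr(gpr)
    if g.body is None:
        return []
    families = _minimalize(_disabling(g.body))
    # sanity: every returned set must actually disable the rule
    for s in families:
        assert not g.eval(knockouts=s), f"non-disabling set {sorted(s)} for rule {g.to_string()}"
    return families


def genes_disabling_reaction(reaction: Reaction) -> List[frozenset]:
    """Minimal disabling gene sets of a reaction's GPR ([] when none exists)."""
    return minimal_disabling_gene_sets(reaction.gpr)
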