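"""Search-space preprocessing: blocked reactions, dead ends, the removable set.

Before any tree search the model is reduced and the candidate knockouts are
bounded.  Reactions that can never carry flux under the applied medium
(*blocked*) and reactions stranded by *dead-end* metabolites (species that can
only ever be produced or only ever be consumed) are removed structurally —
this is flux-neutral, so the reduced model keeps the wild-type growth optimum.
The remaining candidates are filtered down to the *removable* set: exchanges
and other boundary reactions are never genetic interventions, the objective
reaction is not a candidate, reactions whose single knockout drops growth
below ``cutoff_fraction x gr_WT`` are *essential*, a user exclusion list is
honoured, and in gene mode reactions without a gene association are dropped
because no gene deletion can remove them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import FrozenSet, Iterable, Optional, Set, Union

import numpy as np
from cobra import Model

from .errors import InfeasibleModelError
from .io import exchange_reactions
from .lp import LPCounter, ZERO_TOL, knockout_context, run_fva, solve_fba


@dataclass(frozen=True)
class PreprocessConfig:
    """Exclusion rules applied when building the removable set."""

    biomass_cutoff_fraction: float = 0.01
    exclude: FrozenSet[str] = frozenset()
    gene_mode: bool = False


@dataclass
class PreprocessReport:
    """Everything the reduction produced, ready for serialization."""

    blocked: FrozenSet[str]
    dead_end_metabolites: FrozenSet[str]
    orphaned: FrozenSet[str]
    essential: FrozenSet[str]
    removable: FrozenSet[str]
    reduced_model: Model
    gr_wt: float

    def to_json(self, path: Union[str, Path, None] = None) -> str:
        payload = {
            "blocked": sorted(self.blocked),
            "dead_end_metabolites": sorted(self.dead_end_metabolites),
            "orphaned": sorted(self.orphaned),
            "essential": sorted(self.essential),
            "removable": sorted(self.removable),
            "gr_wt": self.gr_wt,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def find_blocked_reactions(model: Model, counter: Optional[LPCounter] = None) -> Set[str]:
    """Reactions whose unconstrained FVA range is [0, 0] within tolerance."""
    fva = run_fva(model, objective_fraction=0.0, counter=counter)
    width = np.maximum(fva["maximum"].abs(), fva["minimum"].abs())
    return set(fva.index[width <= ZERO_TOL])


def find_dead_end_metabolites(model: Model, ignore_reactions: Iterable[str] = ()) -> Set[str]:
    """Metabolites that can only be produced or only be consumed, to a fixed point.

    Purely structural: a reversible reaction (lb < 0) counts in both
    directions.  Removing a dead end strands its neighbouring reactions, which
    may expose further dead ends; iteration continues until nothing changes.
    ``ignore_reactions`` lets callers pre-remove blocked reactions.
    """
    inactive = set(ignore_reactions)
    dead: Set[str] = set()
    changed = True
    while changed:
        changed = False
        for met in model.metabolites:
            if met.id in dead:
                continue
            can_produce = can_consume = False
            for rxn in met.reactions:
                if rxn.id in inactive:
                    continue
                coef = rxn.metabolites[met]
                if (coef > 0 and rxn.upper_bound > 0) or (coef < 0 and rxn.lower_bound < 0):
                    can_produce = True
                if (coef < 0 and rxn.upper_bound > 0) or (coef > 0 and rxn.lower_bound < 0):
                    can_consume = True
                if can_produce and can_consume:
                    break
            if not (can_produce and can_consume):
                dead.add(met.id)
                for rxn in met.reactions:
                    if rxn.id not in inactive:
                        inactive.add(rxn.id)
                        changed = True
    return dead


def _orphaned_by_dead_ends(model: Model, dead_mets: Set[str], already: Set[str]) -> Set[str]:
    out: Set[str] = set()
    for mid in dead_mets:
        for rxn in model.metabolites.get_by_id(mid).reactions:
            if rxn.id not in already:
                out.add(rxn.id)
    return out


def compute_removable_set(
    model: Model,
    config: PreprocessConfig = PreprocessConfig(),
    counter: Optional[LPCounter] = None,
) -> PreprocessReport:
    """Build the reduced model and the removable candidate-knockout set.

    The medium must already be applied.  Essentiality of each surviving
    candidate is probed with one FBA per reaction against the growth floor
    ``biomass_cutoff_fraction x gr_WT``.
    """
    base = solve_fba(model, counter=counter)
    if not base.ok or base.objective_value is None:
        raise InfeasibleModelError("cannot preprocess an infeasible model")
    gr_wt = base.objective_value

    blocked = find_blocked_reactions(model, counter=counter)
    dead_mets = find_dead_end_metabolites(model, ignore_reactions=blocked)
    orphaned = _orphaned_by_dead_ends(model, dead_mets, blocked)

    reduced = model.copy()
    to_remove = [reduced.reactions.get_by_id(rid) for rid in sorted(blocked | orphaned)]
    if to_remove:
        reduced.remove_reactions(to_remove, remove_orphans=True)

    boundary = {r.id for r in reduced.boundary}
    boundary |= {r.id for r in exchange_reactions(reduced)}
    objective_ids = {r.id for r in reduced.reactions if r.objective_coefficient}

    candidates = []
    for rxn in reduced.reactions:
        if rxn.id in boundary or rxn.id in objective_ids or rxn.id in config.exclude:
            continue
        if config.gene_mode and rxn.gpr.body is None:
            continue
        candidates.append(rxn.id)

    floor = config.biomass_cutoff_fraction * gr_wt
    essential: Set[str] = set()
    for rid in sorted(candidates):
        with knockout_context(reduced, [rid]):
            growth = reduced.slim_optimize(error_value=float("nan"))
        if counter is not None:
            counter.node_lps += 1
        if np.isnan(growth) or growth < floor - ZERO_TOL:
            essential.add(rid)

    removable = frozenset(set(candidates) - essential)
    return PreprocessReport(
        blocked=frozenset(blocked),
        dead_end_metabolites=frozenset(dead_mets),
        orphaned=frozenset(orphaned),
        essential=frozenset(essential),
        removable=removable,
        reduced_model=reduced,
        gr_wt=gr_wt,
    )
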