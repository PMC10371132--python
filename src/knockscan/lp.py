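"""Linear-programming primitives shared by every stage of the pipeline.

All higher-level routines (preprocessing, tree search, strain metrics) reduce
to four operations on a constraint-based model: flux balance analysis (FBA),
flux variability analysis (FVA), applying reaction knockouts, and querying the
product-flux range while growth is pinned to its optimum.  They are collected
here so that LP accounting is consistent: every node-level FBA increments
``LPCounter.node_lps`` and every variability sub-problem increments
``LPCounter.fva_lps``.

Models are plain :class:`cobra.Model` objects; the GLPK backend shipped with
COBRApy is deterministic for a fixed model, so repeated runs on one machine
return the same optimal vertex.
"""

from __future__ import annotations

from contextlib import contextmanager
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from cobra import Model

from .errors import ConfigurationError, InfeasibleModelError, SolverStateError

#: fluxes with magnitude at or below this are treated as zero
ZERO_TOL = 1e-6

#: relative slack used when pinning an objective to its optimum; a strict
#: equality can render the problem empty under floating-point ties
OPTIMUM_SLACK = 1e-9

_OK_STATUSES = {"optimal"}
_INFEASIBLE_STATUSES = {"infeasible", "undefined"}


@dataclass
class LPCounter:
    """Tally of LPs solved, split by role.

    ``node_lps`` counts one FBA per traversal-tree node (the paper-style
    accounting in which the LP count equals the node count); ``fva_lps``
    counts every min/max sub-problem of a variability analysis.
    """

    node_lps: int = 0
    fva_lps: int = 0

    @property
    def total(self) -> int:
        return self.node_lps + self.fva_lps


@dataclass
class FluxResult:
    """Outcome of a single FBA solve."""

    status: str
    objective_value: Optional[float]
    fluxes: Optional[pd.Series]

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


@dataclass
class ProductRates:
    """Growth optimum plus the product-flux range attainable at that optimum."""

    growth: float
    product_min: float
    product_max: float


def _objective_reaction(model: Model):
    """Return the single reaction carrying the model objective."""
    rxns = [r for r in model.reactions if r.objective_coefficient]
    if len(rxns) != 1:
        raise ConfigurationError(
            f"expected exactly one objective reaction, found {len(rxns)}"
        )
    return rxns[0]


def solve_fba(
    model: Model,
    objective_id: Optional[str] = None,
    sense: str = "max",
    counter: Optional[LPCounter] = None,
) -> FluxResult:
    """Flux balance analysis with an optional temporary objective.

    Returns a :class:`FluxResult` whose status is ``optimal`` or
    ``infeasible``; solver statuses that signal numerical trouble raise
    :class:`SolverStateError` instead so they are never mistaken for a
    genuinely empty feasible region.
    """
    if sense not in ("max", "min"):
        raise ValueError(f"sense must be 'max' or 'min', got {sense!r}")
    with model:
        if objective_id is not None:
            if objective_id not in model.reactions:
                raise ConfigurationError(f"unknown objective reaction {objective_id!r}")
            model.objective = objective_id
        model.objective_direction = "max" if sense == "max" else "min"
        solution = model.optimize(raise_error=False)
    if counter is not None:
        counter.node_lps += 1
    if solution.status in _OK_STATUSES:
        return FluxResult("optimal", float(solution.objective_value), solution.fluxes)
    if solution.status in _INFEASIBLE_STATUSES:
        return FluxResult("infeasible", None, None)
    raise SolverStateError(f"solver returned status {solution.status!r}")


def _slim(model: Model) -> float:
    """``slim_optimize`` returning NaN on infeasibility."""
    return model.slim_optimize(error_value=float("nan"))


def _pin_objective(model: Model, fraction: float, counter: Optional[LPCounter]) -> float:
    """Constrain the current objective to ``fraction`` of its optimum.

    Must be called inside a model context.  Returns the optimum.  At
    ``fraction == 1`` a relative slack of ``OPTIMUM_SLACK`` is kept so the
    pinned problem stays feasible under floating-point ties.
    """
    opt = _slim(model)
    if counter is not None:
        counter.fva_lps += 1
    if np.isnan(opt):
        raise InfeasibleModelError("base model is infeasible; cannot pin objective")
    if fraction > 0:
        bound = fraction * opt - OPTIMUM_SLACK * max(1.0, abs(opt))
        obj_rxn = _objective_reaction(model)
        if bound > obj_rxn.lower_bound:
            obj_rxn.lower_bound = bound
    return float(opt)


def run_fva(
    model: Model,
    reaction_ids: Optional[Iterable[str]] = None,
    objective_fraction: float = 0.0,
    counter: Optional[LPCounter] = None,
) -> pd.DataFrame:
    """Flux variability analysis.

    For every reaction in ``reaction_ids`` (default: all reactions) the
    minimum and maximum flux is computed subject to the model objective being
    at least ``objective_fraction`` times its optimum; two LPs per reaction.
    Returns a DataFrame indexed by reaction id with ``minimum``/``maximum``
    columns.
    """
    if not 0.0 <= objective_fraction <= 1.0:
        raise ValueError("objective_fraction must lie in [0, 1]")
    if reaction_ids is None:
        rids = [r.id for r in model.reactions]
    else:
        rids = sorted(reaction_ids)
        for rid in rids:
            if rid not in model.reactions:
                raise ConfigurationError(f"unknown reaction {rid!r}")
    lo = np.empty(len(rids))
    hi = np.empty(len(rids))
    with model:
        if objective_fraction > 0:
            _pin_objective(model, objective_fraction, counter)
        for i, rid in enumerate(rids):
            rxn = model.reactions.get_by_id(rid)
            model.objective = rxn
            model.objective_direction = "min"
            lo[i] = _slim(model)
            model.objective_direction = "max"
            hi[i] = _slim(model)
            if counter is not None:
                counter.fva_lps += 2
    if np.isnan(lo).any() or np.isnan(hi).any():
        raise InfeasibleModelError("FVA sub-problem infeasible; base model has no flux state")
    return pd.DataFrame({"minimum": lo, "maximum": hi}, index=pd.Index(rids, name="reaction"))


def apply_knockouts(model: Model, reaction_ids: Iterable[str]) -> Model:
    """Return a copy of ``model`` with the listed reactions forced to zero flux.

    The original model is left untouched.  Unknown ids raise
    :class:`ConfigurationError` naming the first offender.
    """
    rids = list(reaction_ids)
    for rid in rids:
        if rid not in model.reactions:
            raise ConfigurationError(f"unknown reaction {rid!r} in knockout set")
    ko = model.copy()
    for rid in rids:
        ko.reactions.get_by_id(rid).bounds = (0.0, 0.0)
    return ko


@contextmanager
def knockout_context(model: Model, reaction_ids: Iterable[str]) -> Iterator[Model]:
    """Temporarily zero the bounds of ``reaction_ids`` (reverted on exit).

    Cheaper than :func:`apply_knockouts` inside tight loops because no model
    copy is made; relies on COBRApy's history manager.
    """
    with model:
        for rid in reaction_ids:
            model.reactions.get_by_id(rid).bounds = (0.0, 0.0)
        yield model


def product_rates_at_optimal_growth(
    model: Model,
    product_exchange_id: str,
    counter: Optional[LPCounter] = None,
    growth: Optional[float] = None,
) -> ProductRates:
    """Growth optimum and the product-exchange flux range at that optimum.

    The growth objective is pinned to ``(1 - 1e-9) x`` its optimum and the
    product exchange is minimized/maximized (2 LPs).  ``growth`` may be
    supplied when the caller has already solved the node FBA, saving one LP.
    Raises :class:`InfeasibleModelError` if the model admits no flux state.
    """
    if product_exchange_id not in model.reactions:
        raise ConfigurationError(f"unknown product exchange {product_exchange_id!r}")
    with model:
        if growth is None:
            growth = _pin_objective(model, 1.0, counter)
        else:
            obj_rxn = _objective_reaction(model)
            bound = growth - OPTIMUM_SLACK * max(1.0, abs(growth))
            if bound > obj_rxn.lower_bound:
                obj_rxn.lower_bound = bound
        product = model.reactions.get_by_id(product_exchange_id)
        model.objective = product
        model.objective_direction = "min"
        pmin = _slim(model)
        model.objective_direction = "max"
        pmax = _slim(model)
        if counter is not None:
            counter.fva_lps += 2
    if np.isnan(pmin) or np.isnan(pmax):
        raise InfeasibleModelError("product FVA infeasible at the pinned growth optimum")
    return ProductRates(growth=float(growth), product_min=float(pmin), product_max=float(pmax))


def steady_state_residual(model: Model, fluxes: Mapping[str, float]) -> float:
    """Largest metabolite imbalance |S.v| of a flux vector (consistency check)."""
    imbalance: dict[str, float] = {m.id: 0.0 for m in model.metabolites}
    for rxn in model.reactions:
        v = fluxes[rxn.id] if rxn.id in fluxes else 0.0
        for met, coef in rxn.metabolites.items():
            imbalance[met.id] += coef * v
    return max((abs(x) for x in imbalance.values()), default=0.0)
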