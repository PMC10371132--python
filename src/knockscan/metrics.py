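"""Post-enumeration strain evaluation.

Once strategies are enumerated they are ranked, not re-searched.  This module
computes the standard strain-design indices:

* the **production envelope** — minimum and maximum product flux as a function
  of growth rate; its lower edge reveals whether production is enforced by
  growth;
* **yield** Y_P/S = product rate / substrate uptake rate (mol/mol) and **SSP**,
  a growth-weighted productivity index (growth x product rate by default, with
  the yield-based literature variant behind a flag);
* **SoGC**, the strength of growth coupling: Y_P/S squared divided by the
  slope of the final linear segment of the envelope's lower edge — a steep
  mandatory rise of production near the growth optimum means little coupling
  benefit over the rest of the envelope, hence the division;
* the **CO2 exchange flux** compatible with maximal production at optimal
  growth, reported as a fixed-growth fixed-product FVA range plus midpoint
  because the flux state there is generally degenerate (negative = uptake);
* **linear MOMA** — the post-knockout flux state minimizing the L1 distance to
  a wild-type flux distribution, the classic model of a cell that reroutes as
  little as possible right after the perturbation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Union

import numpy as np
import pandas as pd
from cobra import Model

from .errors import ConfigurationError, InfeasibleModelError
from .lp import LPCounter, OPTIMUM_SLACK, ZERO_TOL, FluxResult, _objective_reaction, _slim

#: grid resolution of production envelopes
DEFAULT_ENVELOPE_POINTS = 40

#: relative tolerance used when clustering consecutive envelope slopes
_SLOPE_RTOL = 1e-4


@dataclass
class ProductionEnvelope:
    """Min/max product flux on a uniform growth grid from 0 to the optimum."""

    growth: np.ndarray
    product_min: np.ndarray
    product_max: np.ndarray
    product_id: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "growth": self.growth,
                "product_min": self.product_min,
                "product_max": self.product_max,
            }
        )

    @property
    def mu_max(self) -> float:
        return float(self.growth[-1])


@dataclass
class SoGCResult:
    value: float
    yield_at_mu_max: float
    lower_edge_slope: float
    flagged: bool  # True when the lower edge is flat/declining and SoGC is reported as 0


@dataclass
class CO2Result:
    minimum: float
    maximum: float
    midpoint: float


@dataclass
class MomaResult:
    status: str
    distance: Optional[float]
    fluxes: Optional[pd.Series]

    def flux(self, reaction_id: str) -> float:
        if self.fluxes is None:
            raise InfeasibleModelError("MOMA problem was infeasible; no fluxes")
        return float(self.fluxes[reaction_id])


def production_envelope(
    model: Model,
    product_exchange_id: str,
    n_points: int = DEFAULT_ENVELOPE_POINTS,
    counter: Optional[LPCounter] = None,
) -> ProductionEnvelope:
    """Product flux range at each growth value of a uniform grid (2 LPs/point)."""
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if product_exchange_id not in model.reactions:
        raise ConfigurationError(f"unknown product exchange {product_exchange_id!r}")
    mu_max = model.slim_optimize(error_value=float("nan"))
    if counter is not None:
        counter.fva_lps += 1
    if np.isnan(mu_max):
        raise InfeasibleModelError("model infeasible; no production envelope")
    grid = np.linspace(0.0, float(mu_max), n_points)
    slack = OPTIMUM_SLACK * max(1.0, abs(mu_max))
    lo = np.empty(n_points)
    hi = np.empty(n_points)
    obj_rxn = _objective_reaction(model)
    product = model.reactions.get_by_id(product_exchange_id)
    with model:
        for i, g in enumerate(grid):
            with model:
                obj_rxn.bounds = (g - slack, g + slack)
                model.objective = product
                model.objective_direction = "min"
                lo[i] = _slim(model)
                model.objective_direction = "max"
                hi[i] = _slim(model)
            if counter is not None:
                counter.fva_lps += 2
    if np.isnan(lo).any() or np.isnan(hi).any():
        raise InfeasibleModelError("an envelope point was infeasible")
    return ProductionEnvelope(grid, lo, hi, product_exchange_id)


def _final_segment_slope(growth: np.ndarray, lower: np.ndarray) -> float:
    """Slope of the last linear piece of the lower edge, found by walking
    breakpoints backwards from the growth optimum."""
    slopes = np.diff(lower) / np.diff(growth)
    last = slopes[-1]
    j = len(slopes) - 1
    scale = max(abs(last), 1.0)
    while j > 0 and abs(slopes[j - 1] - last) <= _SLOPE_RTOL * scale:
        j -= 1
    return float((lower[-1] - lower[j]) / (growth[-1] - growth[j]))


def compute_sogc(
    envelope: ProductionEnvelope,
    substrate_uptake: float,
    slope_method: str = "breakpoints",
) -> SoGCResult:
    """Strength of growth coupling from an envelope.

    ``substrate_uptake`` is the (positive) substrate uptake magnitude used for
    the yield.  ``slope_method`` is ``breakpoints`` (slope of the detected
    final linear segment of the lower edge, default) or ``two_point`` (finite
    difference over the last grid interval).  A flat or declining lower edge
    means production is not enforced by growth; SoGC is then 0 and flagged.
    """
    if substrate_uptake <= 0:
        raise ValueError("substrate_uptake must be positive")
    if envelope.mu_max <= ZERO_TOL:
        raise InfeasibleModelError("degenerate envelope: growth optimum is ~0")
    y = float(envelope.product_min[-1]) / substrate_uptake
    if slope_method == "breakpoints":
        slope = _final_segment_slope(envelope.growth, envelope.product_min)
    elif slope_method == "two_point":
        slope = float(
            (envelope.product_min[-1] - envelope.product_min[-2])
            / (envelope.growth[-1] - envelope.growth[-2])
        )
    else:
        raise ValueError(f"unknown slope_method {slope_method!r}")
    if slope <= ZERO_TOL:
        return SoGCResult(0.0, y, slope, flagged=True)
    return SoGCResult(y * y / slope, y, slope, flagged=False)


def compute_yield_ssp(
    growth: float,
    product_rate: float,
    substrate_uptake: float,
    ssp_definition: str = "rate",
) -> tuple[float, float]:
    """Product yield and substrate-specific productivity.

    ``ssp_definition='rate'`` tabulates growth x product rate;
    ``'yield'`` uses the literature variant growth x yield.
    """
    if substrate_uptake <= 0:
        raise ValueError("substrate_uptake must be positive")
    y = product_rate / substrate_uptake
    if ssp_definition == "rate":
        ssp = growth * product_rate
    elif ssp_definition == "yield":
        ssp = growth * y
    else:
        raise ValueError(f"unknown ssp_definition {ssp_definition!r}")
    return y, ssp


def co2_exchange_flux(
    model: Model,
    product_exchange_id: str,
    co2_exchange_id: str,
    counter: Optional[LPCounter] = None,
) -> CO2Result:
    """CO2 exchange range while growth is optimal and production maximal.

    Growth is pinned to its optimum, the product to its maximum there; the CO2
    exchange is then minimized/maximized.  Negative values are uptake.
    """
    for rid in (product_exchange_id, co2_exchange_id):
        if rid not in model.reactions:
            raise ConfigurationError(f"unknown exchange {rid!r}")
    with model:
        opt = _slim(model)
        if np.isnan(opt):
            raise InfeasibleModelError("model infeasible")
        obj_rxn = _objective_reaction(model)
        obj_rxn.lower_bound = max(
            obj_rxn.lower_bound, opt - OPTIMUM_SLACK * max(1.0, abs(opt))
        )
        product = model.reactions.get_by_id(product_exchange_id)
        model.objective = product
        model.objective_direction = "max"
        pmax = _slim(model)
        product.lower_bound = max(
            product.lower_bound, pmax - OPTIMUM_SLACK * max(1.0, abs(pmax))
        )
        co2 = model.reactions.get_by_id(co2_exchange_id)
        model.objective = co2
        model.objective_direction = "min"
        lo = _slim(model)
        model.objective_direction = "max"
        hi = _slim(model)
        if counter is not None:
            counter.fva_lps += 4
    if np.isnan(lo) or np.isnan(hi):
        raise InfeasibleModelError("CO2 range infeasible at pinned growth/production")
    return CO2Result(float(lo), float(hi), float((lo + hi) / 2.0))


def linear_moma(
    model: Model,
    wild_fluxes: Union[pd.Series, Mapping[str, float], FluxResult],
    knockout_ids: Iterable[str] = (),
) -> MomaResult:
    """Minimize the L1 distance to a wild-type flux distribution.

    Solves ``min sum_r |v_r - v_r^wild|`` over the knockout model's feasible
    set via one split auxiliary variable per reaction (d_r >= |v_r - w_r|).
    The distance runs over *all* reactions, exchanges included.  Returns the
    minimizing flux state; an infeasible knockout model yields status
    ``infeasible`` rather than an exception.
    """
    if isinstance(wild_fluxes, FluxResult):
        if wild_fluxes.fluxes is None:
            raise ValueError("wild_fluxes carries no flux vector")
        wild = wild_fluxes.fluxes
    else:
        wild = pd.Series(dict(wild_fluxes)) if not isinstance(wild_fluxes, pd.Series) else wild_fluxes
    with model:
        for rid in knockout_ids:
            if rid not in model.reactions:
                raise ConfigurationError(f"unknown reaction {rid!r} in knockout set")
            model.reactions.get_by_id(rid).bounds = (0.0, 0.0)
        prob = model.problem
        devs = []
        cons = []
        for rxn in model.reactions:
            w = float(wild.get(rxn.id, 0.0))
            d = prob.Variable(f"moma_dev_{rxn.id}", lb=0.0)
            devs.append(d)
            #  v - d <= w   and   v + d >= w   ==>   d >= |v - w|
            cons.append(prob.Constraint(rxn.flux_expression - d, ub=w, name=f"moma_ub_{rxn.id}"))
            cons.append(prob.Constraint(rxn.flux_expression + d, lb=w, name=f"moma_lb_{rxn.id}"))
        model.add_cons_vars(devs + cons)
        model.objective = prob.Objective(sum(devs), direction="min")
        solution = model.optimize(raise_error=False)
        if solution.status != "optimal":
            return MomaResult("infeasible", None, None)
        return MomaResult("optimal", float(solution.objective_value), solution.fluxes)
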