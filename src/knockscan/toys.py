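"""Synthetic toy metabolic models with a cofactor-coupling motif.

The motif mirrors the situation that makes byproduct-branch knockouts
growth-couple a product: a substrate is taken up and activated
(``EX_A`` -> ``R_UPT``), growth consumes the activated carrier together with a
reduced cofactor NH and returns the oxidized form N (``R_GW``), and the
cofactor can only be re-reduced by either the product branch (``R_P``) or one
of several byproduct branches (``RB*``).  Closing enough byproduct capacity
forces cofactor regeneration through the product branch, so product synthesis
becomes mandatory at any growth rate — exactly the kind of strategy the tree
search must find.

``make_toy1`` is the canonical hand-solvable instance (one byproduct branch,
all capacities open): wild-type growth 5, maximum product rate 5, production
threshold 0.25 at the 5% default, and ``{R4}`` as the unique single-knockout
strategy with guaranteed production.  ``generate_toy_model`` produces seeded
random variants with ``n_branches`` byproduct branches of bounded capacity and
configurable gene rules, used to exercise the search against the exhaustive
oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import cobra
import numpy as np
from cobra import Metabolite, Model, Reaction

from .errors import BudgetExceededError

#: substrate uptake limit shared by all toys (mmol gDW^-1 h^-1)
UPTAKE = 10.0
_BIG = 1000.0


def _add_reaction(model: Model, rid: str, stoich: dict, lb: float, ub: float, gpr: str = "") -> Reaction:
    rxn = Reaction(rid, lower_bound=lb, upper_bound=ub)
    model.add_reactions([rxn])
    rxn.add_metabolites({model.metabolites.get_by_id(m): c for m, c in stoich.items()})
    if gpr:
        rxn.gene_reaction_rule = gpr
    return rxn


def make_toy1() -> Model:
    """The canonical fixture: 4 internal reactions, 1 product, 1 byproduct.

    =========  ==========================  ====
    reaction   chemistry                   gene
    =========  ==========================  ====
    EX_A       A exchange (uptake <= 10)
    R1         A -> B                      g1
    R2         B + NH -> C + N             g2
    R3         B + N  -> P + NH            g3
    R4         B + N  -> D + NH            g4
    EX_P/EX_D  P / D secretion
    BIOMASS    C -> (objective)
    =========  ==========================  ====

    Carbon splits 1:1 between growth (R2) and cofactor regeneration (R3/R4),
    so wild-type growth is 5 and product flux at the optimum ranges over
    [0, 5]; knocking out R4 pins it at 5.
    """
    model = Model("TOY1")
    model.add_metabolites([Metabolite(m, compartment="c") for m in "A B C N NH P D".split()])
    _add_reaction(model, "EX_A", {"A": -1}, -UPTAKE, _BIG)
    _add_reaction(model, "R1", {"A": -1, "B": 1}, 0, _BIG, "g1")
    _add_reaction(model, "R2", {"B": -1, "NH": -1, "C": 1, "N": 1}, 0, _BIG, "g2")
    _add_reaction(model, "R3", {"B": -1, "N": -1, "P": 1, "NH": 1}, 0, _BIG, "g3")
    _add_reaction(model, "R4", {"B": -1, "N": -1, "D": 1, "NH": 1}, 0, _BIG, "g4")
    _add_reaction(model, "EX_P", {"P": -1}, 0, _BIG)
    _add_reaction(model, "EX_D", {"D": -1}, 0, _BIG)
    _add_reaction(model, "BIOMASS", {"C": -1}, 0, _BIG)
    model.objective = "BIOMASS"
    return model


@dataclass(frozen=True)
class ToyModelSpec:
    """Parameters of a randomized toy instance."""

    seed: int
    n_branches: int = 3
    coupling_motif: bool = True
    gpr_style: str = "one-to-one"  # or "shared-gene", "isozyme"

    def __post_init__(self):
        if self.n_branches < 1:
            raise ValueError("n_branches must be >= 1")
        if self.gpr_style not in ("one-to-one", "shared-gene", "isozyme"):
            raise ValueError(f"unknown gpr_style {self.gpr_style!r}")


def generate_toy_model(spec: ToyModelSpec) -> Model:
    """Seeded random variant of the coupling motif.

    Byproduct branches ``RB1..RBn`` get capacities drawn from [2.5, 4.0]
    mmol gDW^-1 h^-1 — wide enough that no single branch can absorb the full
    cofactor flux of 5, narrow enough that any two open branches can, which
    yields a rich mix of qualifying cardinalities across ``n_branches``.
    With ``coupling_motif`` off the byproduct branches skip the cofactor
    (plain ``B -> D_i``), so byproduct knockouts never force production.
    Identical specs produce identical models; an infeasible draw is retried
    with a perturbed stream (never triggered by the current motif, but kept as
    a guard) up to 100 times.
    """
    for attempt in range(100):
        rng = np.random.default_rng((spec.seed, attempt))
        model = _build(spec, rng)
        growth = model.slim_optimize(error_value=0.0)
        with model:
            model.objective = "EX_P"
            v_p = model.slim_optimize(error_value=0.0)
        if growth > 1e-6 and v_p > 1e-6:
            return model
    raise BudgetExceededError(f"no feasible toy model after 100 attempts for {spec}")


def _build(spec: ToyModelSpec, rng: np.random.Generator) -> Model:
    model = Model(f"TOY-s{spec.seed}-b{spec.n_branches}-{spec.gpr_style}")
    mets = ["A", "B", "C", "N", "NH", "P"] + [f"D{i}" for i in range(1, spec.n_branches + 1)]
    model.add_metabolites([Metabolite(m, compartment="c") for m in mets])

    _add_reaction(model, "EX_A", {"A": -1}, -UPTAKE, _BIG)
    _add_reaction(model, "R_UPT", {"A": -1, "B": 1}, 0, _BIG, "g_upt")
    _add_reaction(model, "R_GW", {"B": -1, "NH": -1, "C": 1, "N": 1}, 0, _BIG, "g_gw")
    _add_reaction(model, "BIOMASS", {"C": -1}, 0, _BIG)

    if spec.gpr_style == "isozyme":
        product_gpr = "gp_iso1 or gp_iso2"
    else:
        product_gpr = "g_p"
    _add_reaction(model, "R_P", {"B": -1, "N": -1, "P": 1, "NH": 1}, 0, _BIG, product_gpr)
    _add_reaction(model, "EX_P", {"P": -1}, 0, _BIG)

    caps = rng.uniform(2.5, 4.0, size=spec.n_branches)
    for i in range(1, spec.n_branches + 1):
        met = f"D{i}"
        if spec.coupling_motif:
            stoich = {"B": -1, "N": -1, met: 1, "NH": 1}
        else:
            stoich = {"B": -1, met: 1}
        if spec.gpr_style == "shared-gene" and i <= 2:
            gpr = "g_shared"
        else:
            gpr = f"g_b{i}"
        _add_reaction(model, f"RB{i}", stoich, 0, float(caps[i - 1]), gpr)
        _add_reaction(model, f"EX_D{i}", {met: -1}, 0, _BIG)

    model.objective = "BIOMASS"
    return model
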