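"""Production envelopes, SoGC, yield/SSP, CO2 range, linear MOMA."""

import cobra
import numpy as np
import pandas as pd
import pytest

import knockscan as ks
from knockscan.errors import ConfigurationError, InfeasibleModelError

#: substrate uptake of the toys (mmol gDW^-1 h^-1)
UPTAKE = 10.0


def test_envelope_fully_coupled_strategy(toy1):
    ko = ks.apply_knockouts(toy1, ["R4"])
    env = ks.production_envelope(ko, "EX_P", n_points=21)
    # with the byproduct branch gone, product flux equals growth pointwise
    assert np.allclose(env.product_min, env.growth, atol=1e-6)
    assert np.allclose(env.product_max, env.growth, atol=1e-6)
    assert env.mu_max == pytest.approx(5.0, abs=1e-6)


def test_envelope_wild_type_lower_edge_is_zero(toy1):
    env = ks.production_envelope(toy1, "EX_P", n_points=21)
    assert np.allclose(env.product_min, 0.0, atol=1e-6)
    # the cofactor motif makes production impossible without growth, so the
    # upper edge starts at 0 and reaches the theoretical maximum at mu_max
    assert env.product_max[0] == pytest.approx(0.0, abs=1e-6)
    assert env.product_max[-1] == pytest.approx(5.0, abs=1e-6)


def test_envelope_endpoint_matches_product_rates(toy1):
    ko = ks.apply_knockouts(toy1, ["R4"])
    env = ks.production_envelope(ko, "EX_P")
    rates = ks.product_rates_at_optimal_growth(ko, "EX_P")
    assert env.product_min[-1] == pytest.approx(rates.product_min, abs=1e-5)
    assert env.product_max[-1] == pytest.approx(rates.product_max, abs=1e-5)


def test_sogc_closed_form(toy1):
    """Full coupling in the toy: slope 1, yield 0.5, SoGC = 0.5^2/1 = 0.25."""
    ko = ks.apply_knockouts(toy1, ["R4"])
    env = ks.production_envelope(ko, "EX_P")
    for method in ("breakpoints", "two_point"):
        res = ks.compute_sogc(env, UPTAKE, slope_method=method)
        assert not res.flagged
        assert res.lower_edge_slope == pytest.approx(1.0, abs=1e-6)
        assert res.yield_at_mu_max == pytest.approx(0.5, abs=1e-6)
        assert res.value == pytest.approx(0.25, abs=1e-6)


def test_sogc_flat_lower_edge_is_flagged_zero(toy1):
    env = ks.production_envelope(toy1, "EX_P")
    res = ks.compute_sogc(env, UPTAKE)
    assert res.flagged and res.value == 0.0


def test_sogc_breakpoint_detection_uses_final_segment():
    # piecewise lower edge: flat until growth 2, then slope 2 up to mu_max 4
    growth = np.linspace(0.0, 4.0, 41)
    lower = np.where(growth <= 2.0, 0.0, 2.0 * (growth - 2.0))
    env = ks.ProductionEnvelope(growth, lower, lower + 1.0, "EX_P")
    res = ks.compute_sogc(env, UPTAKE)
    assert res.lower_edge_slope == pytest.approx(2.0, abs=1e-9)
    assert res.value == pytest.approx((4.0 / UPTAKE) ** 2 / 2.0, abs=1e-9)


def test_yield_and_ssp():
    y, ssp = ks.compute_yield_ssp(0.12, 12.24, 10.0)
    assert y == pytest.approx(1.224, abs=1e-9)
    assert ssp == pytest.approx(1.4688, abs=1e-9)
    assert y * 10.0 == pytest.approx(12.24)  # algebraic identity
    y2, ssp2 = ks.compute_yield_ssp(0.12, 12.24, 10.0, ssp_definition="yield")
    assert ssp2 == pytest.approx(0.12 * 1.224)
    assert ks.compute_yield_ssp(5.0, 0.0, 10.0) == (0.0, 0.0)
    with pytest.raises(ValueError):
        ks.compute_yield_ssp(1.0, 1.0, 0.0)


def test_toy_strategy_yield_ssp(toy1):
    rates = ks.product_rates_at_optimal_growth(ks.apply_knockouts(toy1, ["R4"]), "EX_P")
    y, ssp = ks.compute_yield_ssp(rates.growth, rates.product_max, UPTAKE)
    assert y == pytest.approx(0.5, abs=1e-6)
    assert ssp == pytest.approx(25.0, abs=1e-4)


def test_co2_missing_exchange_errors(toy1):
    with pytest.raises(ConfigurationError):
        ks.co2_exchange_flux(toy1, "EX_P", "EX_co2")


def test_co2_closed_exchange_reports_zero(toy1):
    toy1.add_metabolites([cobra.Metabolite("CO2", compartment="c")])
    rxn = cobra.Reaction("EX_co2", lower_bound=0.0, upper_bound=0.0)
    toy1.add_reactions([rxn])
    rxn.add_metabolites({toy1.metabolites.CO2: -1})
    res = ks.co2_exchange_flux(toy1, "EX_P", "EX_co2")
    assert res.minimum == res.maximum == res.midpoint == 0.0


def test_moma_identity_without_knockout(toy1):
    wild = ks.solve_fba(toy1)
    res = ks.linear_moma(toy1, wild)
    assert res.status == "optimal"
    assert res.distance == pytest.approx(0.0, abs=1e-6)


def test_moma_reroutes_through_surviving_branch(toy1):
    """From a wild vertex with v_R4 = 5, removing R4 forces 5 units through R3:
    the internal reroute contributes 10 to the L1 distance and the exchange
    swap (EX_D off, EX_P on) another 10."""
    wild = pd.Series(
        {"EX_A": -10.0, "R1": 10.0, "R2": 5.0, "R3": 0.0, "R4": 5.0,
         "EX_P": 0.0, "EX_D": 5.0, "BIOMASS": 5.0}
    )
    res = ks.linear_moma(toy1, wild, knockout_ids=["R4"])
    assert res.status == "optimal"
    assert res.flux("R3") == pytest.approx(5.0, abs=1e-6)
    assert res.flux("BIOMASS") == pytest.approx(5.0, abs=1e-6)
    assert res.distance == pytest.approx(20.0, abs=1e-6)
    internal = sum(abs(res.flux(r) - wild[r]) for r in ("R1", "R2", "R3", "R4", "BIOMASS"))
    assert internal == pytest.approx(10.0, abs=1e-6)


def test_moma_matches_scipy_oracle(toy1):
    """Independent check: the same L1 projection solved by scipy.linprog."""
    from scipy.optimize import linprog

    wild_vec = {"EX_A": -10.0, "R1": 10.0, "R2": 5.0, "R3": 0.0, "R4": 5.0,
                "EX_P": 0.0, "EX_D": 5.0, "BIOMASS": 5.0}
    ko = ks.apply_knockouts(toy1, ["R4"])
    rids = [r.id for r in ko.reactions]
    mids = [m.id for m in ko.metabolites]
    n = len(rids)
    S = np.zeros((len(mids), n))
    for j, rxn in enumerate(ko.reactions):
        for met, coef in rxn.metabolites.items():
            S[mids.index(met.id), j] = coef
    # variables: v (n) then d (n); minimize sum d  s.t.  S v = 0, -d <= v - w <= d
    c = np.concatenate([np.zeros(n), np.ones(n)])
    A_eq = np.hstack([S, np.zeros_like(S)])
    b_eq = np.zeros(len(mids))
    I = np.eye(n)
    A_ub = np.vstack([np.hstack([I, -I]), np.hstack([-I, -I])])
    w = np.array([wild_vec[r] for r in rids])
    b_ub = np.concatenate([w, -w])
    bounds = [(r.lower_bound, r.upper_bound) for r in ko.reactions] + [(0, None)] * n
    lp = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs")
    assert lp.status == 0
    res = ks.linear_moma(toy1, pd.Series(wild_vec), knockout_ids=["R4"])
    assert res.distance == pytest.approx(lp.fun, abs=1e-6)


def test_moma_agrees_with_cobrapy(toy1):
    """Dual-route check against COBRApy's linear MOMA formulation."""
    from cobra.flux_analysis import moma

    wild = toy1.optimize()
    with ks.knockout_context(toy1, ["R3"]):
        theirs = moma(toy1, solution=wild, linear=True)
        theirs_dist = float(sum(abs(theirs.fluxes[r.id] - wild.fluxes[r.id]) for r in toy1.reactions))
    ours = ks.linear_moma(toy1, wild.fluxes, knockout_ids=["R3"])
    assert ours.distance == pytest.approx(theirs_dist, abs=1e-6)


def test_moma_infeasible_knockout(toy1):
    toy1.reactions.BIOMASS.lower_bound = 1.0  # demand growth, then cut the route
    wild = ks.solve_fba(toy1)
    res = ks.linear_moma(toy1, wild, knockout_ids=["R1"])
    assert res.status == "infeasible"
    assert res.distance is None


def test_moma_distance_bounded_by_wild_l1(toy1):
    wild = ks.solve_fba(toy1)
    total = float(wild.fluxes.abs().sum())
    for rid in ("R3", "R4"):
        res = ks.linear_moma(toy1, wild, knockout_ids=[rid])
        assert res.distance <= total + 1e-6
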