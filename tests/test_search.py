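"""Thresholds, target spaces, tree construction, traversal, qualification."""

import pytest

import knockscan as ks
from knockscan.errors import ConfigurationError
from knockscan.search import Node

from conftest import toy_and_removable


def test_thresholds_on_toy(toy1, grnt_config):
    th = ks.compute_thresholds(toy1, "EX_P", grnt_config)
    assert th.gr_wt == pytest.approx(5.0)
    assert th.v_chemical == pytest.approx(5.0)
    assert th.th_chemical == pytest.approx(0.25)
    assert th.biomass_floor == pytest.approx(0.05)


def test_degenerate_threshold_warns_and_everything_qualifies(toy1, grnt_config):
    # close the product exchange: max theoretical rate collapses to 0
    toy1.reactions.EX_P.bounds = (0.0, 0.0)
    with pytest.warns(UserWarning, match="degenerates"):
        th = ks.compute_thresholds(toy1, "EX_P", grnt_config)
    assert th.th_chemical == 0.0
    # any growth-viable knockout now trivially clears the zero threshold
    with ks.knockout_context(toy1, ["R3"]):
        rec = ks.qualify_solution(toy1, "EX_P", frozenset({"R3"}), th, "rate_grnt")
    assert rec is not None and rec.qualifying_mode == "both"
    # ... but with product export closed, R3 is blocked (kept out of every
    # target space) and deleting R4 starves the cofactor cycle, so the
    # traversal itself finds nothing
    result = ks.traverse_tree(toy1, {"R3", "R4"}, "EX_P", grnt_config)
    assert result.solutions == []


def test_target_space_fva_sees_both_branches(toy1):
    ts, flux = ks.identify_target_space(
        toy1, frozenset(), frozenset({"R3", "R4"}), rule="fva_support"
    )
    assert ts == {"R3", "R4"}
    assert flux.ok


def test_target_space_fba_picks_a_single_vertex(toy1):
    """With a degenerate optimum the FBA rule sees only the solver's vertex."""
    ts, _ = ks.identify_target_space(
        toy1, frozenset(), frozenset({"R3", "R4"}), rule="fba_support"
    )
    assert ts in ({"R3"}, {"R4"}, {"R3", "R4"})
    assert len(ts) >= 1


def test_target_space_empty_when_growth_dies(toy1):
    with ks.knockout_context(toy1, ["R1"]):
        ts, flux = ks.identify_target_space(
            toy1, frozenset({"R1"}), frozenset({"R3", "R4"}), rule="fva_support"
        )
    # growth-dead node: the optimum is 0, no removable reaction can carry flux
    assert ts == frozenset()


def test_construct_subtree_children_and_checked():
    node = Node(level=0, deleted_rxns=frozenset(), target_space=frozenset({"R3", "R4"}))
    children = ks.construct_subtree(node)
    assert [sorted(c.deleted_rxns) for c in children] == [["R3"], ["R4"]]
    assert all(c.level == 1 for c in children)
    only_r4 = ks.construct_subtree(node, checked={"R3"})
    assert [sorted(c.deleted_rxns) for c in only_r4] == [["R4"]]
    leaf = Node(level=2, deleted_rxns=frozenset({"a", "b"}), target_space=frozenset())
    assert ks.construct_subtree(leaf) == []


def test_traverse_finds_unique_single_solution(toy1, grnt_config):
    result = ks.traverse_tree(toy1, {"R3", "R4"}, "EX_P", grnt_config)
    assert [s.reactions for s in result.solutions] == [("R4",)]
    sol = result.solutions[0]
    assert sol.growth == pytest.approx(5.0, abs=1e-6)
    assert sol.product_min == pytest.approx(5.0, abs=1e-6)
    assert sol.qualifying_mode == "both"
    assert result.node_count == result.lp_count


def test_traverse_empty_removable(toy1, grnt_config):
    result = ks.traverse_tree(toy1, set(), "EX_P", grnt_config)
    assert result.solutions == []
    assert result.node_count == 1  # just the root


def test_traverse_rejects_bad_config(toy1):
    with pytest.raises(ConfigurationError):
        ks.TraversalConfig(target_level=0)
    with pytest.raises(ConfigurationError):
        ks.TraversalConfig(target_level=99)
    with pytest.raises(ConfigurationError):
        ks.TraversalConfig(mode="rate_best")
    with pytest.raises(ConfigurationError):
        ks.traverse_tree(toy1, {"R4"}, "EX_NOPE", ks.TraversalConfig())


def test_qualification_examples(toy1, grnt_config):
    th = ks.compute_thresholds(toy1, "EX_P", grnt_config)
    with ks.knockout_context(toy1, ["R3"]):
        rec = ks.qualify_solution(toy1, "EX_P", frozenset({"R3"}), th, "rate_max")
    assert rec is None  # product is unreachable without R3
    with ks.knockout_context(toy1, ["R4"]):
        rec = ks.qualify_solution(toy1, "EX_P", frozenset({"R4"}), th, "rate_grnt")
    assert rec is not None and rec.product_min >= th.th_chemical


@pytest.mark.parametrize("seed,n_branches", [(3, 2), (3, 3)])
def test_guaranteed_solutions_subset_of_max(seed, n_branches):
    model, removable = toy_and_removable(seed, n_branches)
    cfg = ks.TraversalConfig(target_level=2, mode="rate_grnt")
    grnt = ks.traverse_tree(model, removable, "EX_P", cfg)
    cfg_max = ks.TraversalConfig(target_level=2, mode="rate_max")
    rmax = ks.traverse_tree(model, removable, "EX_P", cfg_max)
    grnt_sets = set(grnt.raw_solutions)
    max_sets = set(rmax.raw_solutions)
    assert grnt_sets <= max_sets
    for level in (1, 2):
        assert sum(1 for s in grnt_sets if len(s) == level) <= sum(
            1 for s in max_sets if len(s) == level
        )


def test_solutions_duplicate_free_and_sorted(toy1):
    model, removable = toy_and_removable(11, 4)
    cfg = ks.TraversalConfig(target_level=3, mode="rate_grnt")
    result = ks.traverse_tree(model, removable, "EX_P", cfg)
    keys = [s.reactions for s in result.solutions]
    assert len(keys) == len(set(keys))
    assert all(tuple(sorted(k)) == k for k in keys)


def test_pinned_reactions_reduce_the_problem():
    model, removable = toy_and_removable(5, 3)
    # pinning one byproduct branch turns the pair solutions into singles
    cfg = ks.TraversalConfig(target_level=1, mode="rate_grnt", pinned=frozenset({"RB1"}))
    result = ks.traverse_tree(model, removable, "EX_P", cfg)
    assert sorted(s.reactions for s in result.solutions) == [("RB2",), ("RB3",)]


def test_minimality_filter_drops_supersets():
    raw = {}
    make = lambda rxns: ks.SolutionRecord(
        reactions=tuple(sorted(rxns)), level=len(rxns), growth=1.0,
        product_min=1.0, product_max=1.0, qualifying_mode="both",
    )
    for rxns in ({"a"}, {"a", "b"}, {"b", "c"}):
        raw[frozenset(rxns)] = make(rxns)
    minimal = ks.minimal_solutions(raw)
    assert sorted(s.reactions for s in minimal) == [("a",), ("b", "c")]


def test_fba_rule_can_hide_a_solution_that_fva_rule_finds(toy1, grnt_config):
    """Documents why fva_support is the default: under a degenerate optimum
    the single FBA vertex may leave the qualifying branch out of the target
    space, whereas the variability rule cannot."""
    import dataclasses

    fva_cfg = grnt_config
    fba_cfg = dataclasses.replace(grnt_config, target_space_rule="fba_support")
    fva_res = ks.traverse_tree(toy1, {"R3", "R4"}, "EX_P", fva_cfg)
    fba_res = ks.traverse_tree(toy1, {"R3", "R4"}, "EX_P", fba_cfg)
    fva_sets = {s.reactions for s in fva_res.solutions}
    fba_sets = {s.reactions for s in fba_res.solutions}
    assert fva_sets == {("R4",)}
    assert fba_sets <= fva_sets  # never invents solutions; may miss under degeneracy
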