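import pytest

from edgefill import (
    ReferenceInteractionSet,
    incident_predicted_edges,
    rank,
    select_candidates,
    set_difference_table,
    validate_edges,
)


def ranking_from_order(order, method=""):
    return rank({p: float(len(order) - i) for i, p in enumerate(order)}, method)


P = [f"P{i:02d}" for i in range(20)]


class TestSetDifferenceTable:
    def test_identical_rankings(self):
        r = ranking_from_order(P, "DC")
        row = set_difference_table(r, r, 5, set(P[:3]))
        assert row.intersection == 5 and row.new_only == 0 and row.ori_only == 0
        assert row.intersection_essential == 3

    def test_disjoint_topk_sets(self):
        r1 = ranking_from_order(P, "DC")
        r2 = ranking_from_order(P[::-1], "DC")
        row = set_difference_table(r1, r2, 5, set())
        assert row.intersection == 0
        assert row.new_only == 5 and row.ori_only == 5

    def test_cells_equal_naive_set_arithmetic(self):
        import numpy as np

        rng = np.random.default_rng(6)
        order1 = list(rng.permutation(P))
        order2 = list(rng.permutation(P))
        ess = set(rng.choice(P, size=7, replace=False))
        k = 8
        row = set_difference_table(
            ranking_from_order(order1, "NC"), ranking_from_order(order2, "NC"), k, ess
        )
        top1, top2 = set(order1[:k]), set(order2[:k])
        assert row.intersection_essential == len(top1 & top2 & ess)
        assert row.new_only_essential == len((top2 - top1) & ess)
        assert row.ori_only_essential == len((top1 - top2) & ess)
        assert row.intersection_nonessential == len((top1 & top2) - ess)
        assert row.new_only_nonessential == len((top2 - top1) - ess)
        assert row.ori_only_nonessential == len((top1 - top2) - ess)
        # structural identities
        assert row.intersection + row.new_only == k
        assert row.intersection + row.ori_only == k

    def test_cutoff_larger_than_ranking_raises(self):
        r = ranking_from_order(P[:5])
        with pytest.raises(ValueError):
            set_difference_table(r, r, 10, set())


def make_rankings(ori_order, new1_order, new2_order, methods=("DC", "NC", "SC")):
    return (
        {m: ranking_from_order(ori_order, m) for m in methods},
        {m: ranking_from_order(new1_order, m) for m in methods},
        {m: ranking_from_order(new2_order, m) for m in methods},
    )


class TestSelectCandidates:
    def test_rescued_essential_protein_selected_nonessential_not(self):
        # X (essential) and Y (non-essential) both jump into the top 3 only
        # under the augmented networks
        ori = ["A", "B", "C", "D", "E", "X", "Y"]
        new = ["X", "Y", "A", "B", "C", "D", "E"]
        r_ori, r_new1, r_new2 = make_rankings(ori, new, new)
        got = select_candidates(
            r_ori, r_new1, r_new2, {"X"}, k=3, rank_threshold=5
        )
        assert [c.protein for c in got] == ["X"]
        assert got[0].deep_ranked  # original rank 6 > 5 under every method
        assert got[0].ori_ranks == {"DC": 6, "NC": 6, "SC": 6}

    def test_protein_in_original_topk_excluded(self):
        ori = ["X", "B", "C", "D"]
        new = ["X", "B", "C", "D"]
        r_ori, r_new1, r_new2 = make_rankings(ori, new, new)
        assert select_candidates(r_ori, r_new1, r_new2, {"X"}, k=2,
                                 rank_threshold=2) == []

    def test_must_qualify_in_both_new_networks(self):
        ori = ["A", "B", "C", "X"]
        new1 = ["X", "A", "B", "C"]
        new2 = ["A", "B", "C", "X"]  # X not in top-2 here
        r_ori, r_new1, r_new2 = make_rankings(ori, new1, new2)
        assert select_candidates(r_ori, r_new1, r_new2, {"X"}, k=2,
                                 rank_threshold=2) == []

    def test_deep_rank_quantifier_all_vs_any(self):
        # X's original ranks differ by method: deep under NC only
        ori_dc = ["A", "B", "X", "C", "D"]
        ori_nc = ["A", "B", "C", "D", "X"]
        new = ["X", "A", "B", "C", "D"]
        r_ori = {"DC": ranking_from_order(ori_dc, "DC"),
                 "NC": ranking_from_order(ori_nc, "NC")}
        r_new1 = {m: ranking_from_order(new, m) for m in ("DC", "NC")}
        r_new2 = {m: ranking_from_order(new, m) for m in ("DC", "NC")}
        all_q = select_candidates(r_ori, r_new1, r_new2, {"X"}, k=2,
                                  rank_threshold=4, deep_quantifier="all")
        any_q = select_candidates(r_ori, r_new1, r_new2, {"X"}, k=2,
                                  rank_threshold=4, deep_quantifier="any")
        assert not all_q[0].deep_ranked  # rank 3 under DC <= 4
        assert any_q[0].deep_ranked  # rank 5 under NC > 4

    def test_invariant_to_method_supply_order(self):
        ori = ["A", "B", "C", "D", "X"]
        new = ["X", "A", "B", "C", "D"]
        methods = ("DC", "NC", "SC")
        r_ori, r_new1, r_new2 = make_rankings(ori, new, new, methods)
        fwd = select_candidates(r_ori, r_new1, r_new2, {"X"}, k=2, rank_threshold=4)
        rev = select_candidates(
            dict(reversed(list(r_ori.items()))),
            dict(reversed(list(r_new1.items()))),
            dict(reversed(list(r_new2.items()))),
            {"X"}, k=2, rank_threshold=4,
        )
        assert [(c.protein, c.deep_ranked) for c in fwd] == [
            (c.protein, c.deep_ranked) for c in rev
        ]

    def test_rank_threshold_below_k_rejected(self):
        r_ori, r_new1, r_new2 = make_rankings(P, P, P)
        with pytest.raises(ValueError):
            select_candidates(r_ori, r_new1, r_new2, set(), k=5, rank_threshold=3)


class TestIncidentPredictedEdges:
    def test_endpoint_filter(self):
        got = incident_predicted_edges({"X"}, {("A", "X"), ("B", "C")})
        assert got == {("A", "X")}

    def test_empty_candidates_give_empty_set(self):
        assert incident_predicted_edges(set(), {("A", "B")}) == set()

    def test_matches_brute_force_endpoint_scan(self, hub_scenario, scenario_params):
        from edgefill import run_two_stage

        s = hub_scenario
        _report, art = run_two_stage(
            s.observed, s.expression, s.annotations, s.dag, s.essential,
            s.reference, scenario_params,
        )
        deep = set(art["deep_ranked"])
        want = {e for e in art["predicted1"] if e[0] in deep or e[1] in deep}
        assert art["selected1"] == want


class TestValidateEdges:
    def test_all_confident_edges_confirmed(self):
        ref = ReferenceInteractionSet(scores={("A", "B"): 0.9, ("C", "D"): 0.9})
        rep = validate_edges({("A", "B"), ("C", "D")}, ref)
        assert rep.n == 2 and rep.confirmed == 2 and rep.fraction == 1.0

    def test_low_confidence_not_confirmed(self):
        ref = ReferenceInteractionSet(scores={("A", "B"): 0.69})
        rep = validate_edges({("A", "B")}, ref, min_conf=0.7)
        assert rep.confirmed == 0

    def test_threshold_inclusive(self):
        ref = ReferenceInteractionSet(scores={("A", "B"): 0.7})
        assert validate_edges({("A", "B")}, ref).confirmed == 1

    def test_empty_group_reports_zero_fraction(self):
        rep = validate_edges(set(), ReferenceInteractionSet())
        assert rep.n == 0 and rep.fraction == 0.0

    def test_matches_brute_force_lookup(self, default_scenario):
        s = default_scenario
        edges = sorted(s.hidden)[:40]
        rep = validate_edges(edges, s.reference, 0.7)
        want = sum(
            1 for e in edges
            if e in s.reference.scores and s.reference.scores[e] >= 0.7
        )
        assert rep.confirmed == want
        assert rep.fraction == pytest.approx(want / len(edges))


def test_selected_precision_beats_random_subset(hub_scenario, scenario_params):
    """Edges incident to deep-ranked candidates are enriched for true hidden
    edges relative to a random equal-sized subset of all predictions."""
    import numpy as np

    from edgefill import run_two_stage, truth_precision

    s = hub_scenario
    _report, art = run_two_stage(
        s.observed, s.expression, s.annotations, s.dag, s.essential,
        s.reference, scenario_params,
    )
    selected = art["selected1"]
    assert selected
    sel_prec, _ = truth_precision(selected, s)
    rng = np.random.default_rng(0)
    all_pred = sorted(art["predicted1"])
    rand_precs = []
    for _ in range(20):
        idx = rng.choice(len(all_pred), size=len(selected), replace=False)
        subset = {all_pred[i] for i in idx}
        rand_precs.append(truth_precision(subset, s)[0])
    assert sel_prec >= float(np.mean(rand_precs))
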