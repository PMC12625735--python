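"""Topology suite: retention χ², edge counts, power law, BIBC, closeness."""

import itertools

import networkx as nx
import numpy as np
import pytest

from conftest import random_disjoint_sets, random_graph
from tknet.exceptions import ValidationError
from tknet.topology import (
    SetCloseness,
    TopologyReport,
    bibc,
    bipartite_edge_count,
    compare_closeness,
    fit_powerlaw,
    retention_comparison,
    set_closeness,
    top_fraction_membership,
)


def bibc_brute_force(graph, set1, set2):
    """Exhaustive shortest-path enumeration oracle."""
    score = dict.fromkeys(graph.nodes, 0.0)
    for s in set1:
        for t in set2:
            if s == t or s not in graph or t not in graph:
                continue
            try:
                paths = list(nx.all_shortest_paths(graph, s, t))
            except nx.NetworkXNoPath:
                continue
            for path in paths:
                for v in path[1:-1]:
                    score[v] += 1.0 / len(paths)
    return score


class TestRetention:
    def test_identical_proportions(self):
        chi2, p = retention_comparison(100, 50, 100, 50)
        assert chi2 == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_hand_computed_chi2(self):
        # table [[90,10],[10,90]]: all expected counts 50 -> chi2 = 4*40^2/50 = 128
        chi2, _ = retention_comparison(100, 90, 100, 10)
        assert chi2 == pytest.approx(128.0)

    def test_symmetric_under_label_swap(self):
        a = retention_comparison(120, 80, 90, 30)
        b = retention_comparison(90, 30, 120, 80)
        assert a == pytest.approx(b)

    def test_zero_margin_gives_missing(self):
        with pytest.warns(UserWarning):
            chi2, p = retention_comparison(10, 0, 10, 0)
        assert np.isnan(chi2) and np.isnan(p)

    def test_retained_cannot_exceed_input(self):
        with pytest.raises(ValidationError):
            retention_comparison(10, 11, 10, 5)


class TestBipartiteEdgeCount:
    def test_star(self):
        g = nx.star_graph(5)
        assert bipartite_edge_count(g, {0}, {1, 2, 3, 4, 5}) == 5

    def test_no_cross_edges(self):
        g = nx.Graph([(0, 1), (2, 3)])
        assert bipartite_edge_count(g, {0, 1}, {2, 3}) == 0

    def test_overlap_rejected(self):
        with pytest.raises(ValidationError):
            bipartite_edge_count(nx.path_graph(3), {0, 1}, {1, 2})

    def test_matches_double_loop_oracle(self, rng):
        for _ in range(20):
            g = random_graph(rng)
            s1, s2 = random_disjoint_sets(rng, g)
            brute = sum(
                1 for u, v in itertools.product(s1, s2) if g.has_edge(u, v)
            )
            assert bipartite_edge_count(g, s1, s2) == brute


class TestPowerlaw:
    def test_exponent_recovery_on_simulated_degrees(self):
        k = np.arange(1, 10**5 + 1)
        p = k**-2.5
        p /= p.sum()
        draws = np.random.default_rng(3).choice(k, size=3000, p=p)
        fit = fit_powerlaw(draws, k_min=4)
        assert 2.2 <= fit.alpha <= 2.8

    def test_star_graph_histogram_two_degrees(self):
        g = nx.star_graph(20)
        fit = fit_powerlaw([d for _, d in g.degree()])
        assert len(fit.histogram) == 2

    def test_duplicating_degrees_leaves_alpha_unchanged(self):
        degs = [1, 1, 2, 3, 5, 8, 13, 1, 2, 4]
        a1 = fit_powerlaw(degs).alpha
        a2 = fit_powerlaw(degs * 2).alpha
        assert a1 == pytest.approx(a2, rel=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValidationError):
            fit_powerlaw([3] * 50)  # all equal
        with pytest.raises(ValidationError):
            fit_powerlaw([1, 2, 3])  # too few


class TestBibc:
    def test_single_geodesic_path(self):
        g = nx.path_graph(["a", "m", "g"])
        scores = bibc(g, {"a"}, {"g"})
        assert scores == {"a": 0.0, "m": 1.0, "g": 0.0}

    def test_diamond_splits_credit(self):
        g = nx.Graph([("a", "m1"), ("a", "m2"), ("m1", "g"), ("m2", "g")])
        scores = bibc(g, {"a"}, {"g"})
        assert scores["m1"] == pytest.approx(0.5)
        assert scores["m2"] == pytest.approx(0.5)

    def test_empty_or_overlapping_sets_rejected(self):
        g = nx.path_graph(3)
        with pytest.raises(ValidationError):
            bibc(g, set(), {2})
        with pytest.raises(ValidationError):
            bibc(g, {0, 1}, {1, 2})

    def test_matches_brute_force_on_random_graphs(self, rng):
        for _ in range(30):
            g = random_graph(rng)
            s1, s2 = random_disjoint_sets(rng, g)
            fast = bibc(g, s1, s2)
            brute = bibc_brute_force(g, s1, s2)
            for node in g.nodes:
                assert fast[node] == pytest.approx(brute[node], abs=1e-9)

    def test_total_equals_sum_of_interior_lengths(self, rng):
        """Σ_v BIBC(v) = Σ over reachable (s,t) pairs of (d(s,t) - 1)."""
        for _ in range(20):
            g = random_graph(rng)
            s1, s2 = random_disjoint_sets(rng, g)
            total = sum(bibc(g, s1, s2).values())
            expected = 0.0
            for s in s1:
                dist = nx.single_source_shortest_path_length(g, s)
                expected += sum(dist[t] - 1 for t in s2 if t in dist)
            assert total == pytest.approx(expected, abs=1e-9)


class TestTopFraction:
    def test_all_top_from_one_group(self):
        scores = {f"a{i}": 10.0 - i for i in range(5)}
        scores.update({f"b{i}": 0.0 for i in range(5)})
        groups = {n: n[0] for n in scores}
        shares = top_fraction_membership(scores, groups, fraction=0.2)
        assert shares == {"a": 1.0, "b": 0.0}

    def test_ceiling_rule_selects_exactly_two_of_ten(self):
        scores = {f"n{i}": float(i) for i in range(10)}
        shares = top_fraction_membership(scores, {n: "g" for n in scores}, 0.20)
        assert shares == {"g": 1.0}  # ceil(0.2*10) = 2 selected, all from g

    def test_tie_break_is_stable_lexicographic(self):
        scores = {n: 1.0 for n in ("b", "a", "d", "c")}
        groups = {"a": "x", "b": "x", "c": "y", "d": "y"}
        shares = top_fraction_membership(scores, groups, fraction=0.5)
        assert shares == {"x": 1.0, "y": 0.0}  # 'a','b' picked by id order

    def test_empty_scores_rejected(self):
        with pytest.raises(ValidationError):
            top_fraction_membership({}, {})


class TestSetCloseness:
    def test_path_graph(self):
        g = nx.path_graph(["a", "m", "g"])
        sc = set_closeness(g, {"a"}, {"g"})
        assert sc.lengths.tolist() == [2.0] and sc.mean == 2.0

    def test_complete_bipartite_all_ones(self):
        g = nx.complete_bipartite_graph(3, 4)
        sc = set_closeness(g, {0, 1, 2}, {3, 4, 5, 6})
        assert sc.mean == 1.0 and sc.n_pairs_used == 12

    def test_unreachable_counted_and_identity_holds(self):
        g = nx.Graph([("a", "b"), ("c", "d")])
        sc = set_closeness(g, {"a", "c"}, {"b", "d"})
        assert sc.n_pairs_used + sc.n_unreachable == 4
        assert sc.n_unreachable == 2

    def test_matches_bfs_oracle_and_symmetry(self, rng):
        for _ in range(15):
            g = random_graph(rng)
            s1, s2 = random_disjoint_sets(rng, g)
            sc = set_closeness(g, s1, s2)
            brute = []
            for s in s1:
                for t in s2:
                    try:
                        brute.append(nx.shortest_path_length(g, s, t))
                    except nx.NetworkXNoPath:
                        pass
            assert sorted(sc.lengths.tolist()) == sorted(float(b) for b in brute)
            rev = set_closeness(g, s2, s1)
            assert sorted(rev.lengths.tolist()) == sorted(sc.lengths.tolist())

    def test_edge_removal_never_shortens_paths(self, rng):
        for _ in range(10):
            g = random_graph(rng, n_max=15, p=0.4)
            if g.number_of_edges() == 0:
                continue
            s1, s2 = random_disjoint_sets(rng, g)
            before = {}
            for s in s1:
                d = nx.single_source_shortest_path_length(g, s)
                before.update({(s, t): d.get(t, np.inf) for t in s2})
            edge = sorted(g.edges)[0]
            g2 = g.copy()
            g2.remove_edge(*edge)
            for s in s1:
                d = nx.single_source_shortest_path_length(g2, s)
                for t in s2:
                    assert d.get(t, np.inf) >= before[(s, t)]


class TestCompareCloseness:
    def test_exact_enumeration_small_case(self):
        _, p = compare_closeness(np.array([1.0, 2.0]), np.array([3.0, 4.0]))
        assert p == pytest.approx(1 / 3)

    def test_identical_distributions_p_one(self):
        _, p = compare_closeness(np.array([1.0, 2.0]), np.array([1.0, 2.0]))
        assert p == pytest.approx(1.0)

    def test_exact_close_to_asymptotic_at_n8(self, rng):
        from scipy import stats

        for _ in range(5):
            x, y = rng.normal(size=8), rng.normal(size=8)
            _, p_exact = compare_closeness(x, y)
            p_asym = stats.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic"
            ).pvalue
            assert abs(p_exact - p_asym) < 0.02

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            compare_closeness(np.array([]), np.array([1.0]))


def test_report_round_trips_through_json():
    report = TopologyReport(
        compartments={"A": {"n_input_features": 10, "n_retained": 5,
                            "retention_proportion": 0.5, "edges_to_layer": {"genes": 3},
                            "closeness": {"genes": SetCloseness(np.array([1.0, 2.0]), 1).to_dict()}}},
        retention_chi2=1.5,
        retention_p=0.2,
        wilcoxon={"genes": {"U": 3.0, "p": 0.4}},
        bibc_top_share={"genes": {"A": 0.7, "B": 0.3}},
    )
    loaded = TopologyReport.from_json(report.to_json())
    # JSON stringifies histogram keys; compare on the serialised form
    assert loaded.to_json(sort_keys=True) == report.to_json(sort_keys=True)
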