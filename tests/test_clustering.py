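"""Cohesiveness objective, greedy growth, quality p and cluster detection."""

import networkx as nx
import numpy as np
import pytest

from seedgcn.clustering import (
    cluster_quality_p,
    cohesiveness,
    density,
    detect_clusters,
    grow_cluster,
    overlap_score,
)

from oracles import exhaustive_best_subset


def test_isolated_edge_is_global_optimum():
    g = nx.Graph([("u", "v")])
    c = grow_cluster(g, "u", penalty=0)
    ref_members, ref_f = exhaustive_best_subset(g.nodes, g.edges, "u", penalty=0)
    assert c.members == frozenset(ref_members)
    assert c.cohesiveness == pytest.approx(ref_f)


def two_cliques_bridge(k=5):
    g = nx.Graph()
    a = [f"A{i}" for i in range(k)]
    b = [f"B{i}" for i in range(k)]
    for side in (a, b):
        g.add_edges_from((u, v) for i, u in enumerate(side) for v in side[i + 1:])
    g.add_edge(a[0], b[0])
    return g, set(a), set(b)


class TestCohesiveness:
    def test_isolated_triangle_values(self):
        g = nx.complete_graph(3)
        assert cohesiveness(g, g.nodes, penalty=0) == pytest.approx(1.0)
        assert cohesiveness(g, g.nodes, penalty=2) == pytest.approx(3 / 9)

    def test_single_vertex_no_internal_edges(self):
        g = nx.path_graph(3)
        assert cohesiveness(g, {1}, penalty=0) == pytest.approx(0.0)

    def test_empty_member_set_rejected(self):
        with pytest.raises(ValueError):
            cohesiveness(nx.path_graph(3), set())

    def test_bounded_and_penalised_by_isolated_vertex(self):
        g = nx.complete_graph(5)
        g.add_node("iso")
        f_core = cohesiveness(g, set(range(5)), penalty=2)
        f_plus = cohesiveness(g, set(range(5)) | {"iso"}, penalty=2)
        assert 0 <= f_plus < f_core <= 1


class TestGrowCluster:
    def test_recovers_clique_from_bridge_graph(self):
        g, a, b = two_cliques_bridge()
        c = grow_cluster(g, "A2", penalty=2)
        assert c.members == frozenset(a)
        # local maximum: no single addition or removal improves f
        f = c.cohesiveness
        for v in g.nodes:
            if v in c.members and v != "A2":
                assert cohesiveness(g, c.members - {v}, 2) <= f + 1e-12
            elif v not in c.members:
                assert cohesiveness(g, c.members | {v}, 2) <= f + 1e-12

    def test_isolated_edge(self):
        g = nx.Graph([("u", "v")])
        c = grow_cluster(g, "u", penalty=0)
        assert c.members == frozenset({"u", "v"})
        assert c.cohesiveness == pytest.approx(1.0)

    def test_isolated_vertex(self):
        g = nx.Graph()
        g.add_node("x")
        c = grow_cluster(g, "x")
        assert c.members == frozenset({"x"})
        assert c.cohesiveness == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_local_optimality_on_small_graphs(self, seed):
        g = nx.gnp_random_graph(9, 0.35, seed=seed)
        if g.number_of_edges() == 0:
            pytest.skip("empty random draw")
        start = max(g.degree, key=lambda kv: kv[1])[0]
        c = grow_cluster(g, start, penalty=2)
        f = c.cohesiveness
        for v in g.nodes:
            if v in c.members and v != start and len(c.members) > 1:
                assert cohesiveness(g, c.members - {v}, 2) <= f + 1e-12
            if v not in c.members:
                assert cohesiveness(g, c.members | {v}, 2) <= f + 1e-12


class TestQualityP:
    def test_isolated_clique_is_significant(self):
        g, a, b = two_cliques_bridge(6)
        assert cluster_quality_p(g, a) < 0.05

    def test_star_fragment_not_significant(self):
        g = nx.star_graph(10)
        assert cluster_quality_p(g, {0, 1}) > 0.5

    def test_degenerate_equal_weights_return_one(self):
        # members with internal weight exactly equal to boundary weight, all tied
        g = nx.Graph([("a", "b"), ("a", "x"), ("b", "y")])
        # internal: a=1, b=1; boundary: a=1, b=1 -> all four values tied
        assert cluster_quality_p(g, {"a", "b"}) == 1.0


class TestDetectClusters:
    def test_two_disjoint_cliques(self):
        g = nx.disjoint_union(nx.complete_graph(6), nx.complete_graph(6))
        clusters = detect_clusters(g)
        assert len(clusters) == 2
        assert all(c.size == 6 and c.density == pytest.approx(1.0) for c in clusters)

    def test_overlap_merge_rule(self):
        a = frozenset(range(5))
        b = frozenset(range(6))
        assert overlap_score(a, b) == pytest.approx(25 / 30)
        assert overlap_score(a, b) > 0.8

    def test_two_clique_bridge_graph_returns_both_cliques(self):
        g, a, b = two_cliques_bridge(6)
        clusters = detect_clusters(g)
        assert {c.members for c in clusters} == {frozenset(a), frozenset(b)}

    def test_output_order_and_density_definition(self):
        g = nx.disjoint_union(nx.complete_graph(7), nx.complete_graph(5))
        clusters = detect_clusters(g)
        assert [c.size for c in clusters] == [7, 5]
        for c in clusters:
            assert c.density == pytest.approx(density(g, c.members))

    def test_relabeling_invariance(self):
        g, a, b = two_cliques_bridge(5)
        mapping = {v: f"Z{v}" for v in g.nodes}
        h = nx.relabel_nodes(g, mapping)
        c_g = {frozenset(mapping[v] for v in c.members) for c in detect_clusters(g)}
        c_h = {c.members for c in detect_clusters(h)}
        assert c_g == c_h
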