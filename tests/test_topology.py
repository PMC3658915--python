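import math

import pytest

from metnet import (
    BFS,
    SBBFS,
    MetabolicNetwork,
    UsageError,
    ValidationError,
    VertexNotFoundError,
    build_network,
    degree_report,
    global_path_metrics,
    neighbors,
    rank_vertices,
    shortest_path,
    single_source_distances,
)
from metnet.network import METABOLITE, REACTION

from _oracles import (
    bfs_distances,
    brute_betweenness,
    brute_closeness,
    constrained_simple_path_distances,
    hits_authority_eig,
    path_respects_set_rule,
)


def toy_path_network(*edges):
    """Metabolite-only CC network from explicit (source, target) pairs."""
    net = MetabolicNetwork("CC")
    for u, v in edges:
        for x in (u, v):
            if not net.has_vertex(x):
                net.add_vertex(x, METABOLITE)
        net.add_edge(u, v)
    return net


class TestDegreeReport:
    def test_diamond_degrees(self, diamond_rc):
        rows = degree_report(diamond_rc).rows.set_index("id")
        assert rows.loc["R1", ["in_degree", "out_degree", "total_degree"]].tolist() == [3, 3, 6]
        assert rows.loc["A", "total_degree"] == 3
        assert rows.loc["B", "total_degree"] == 3
        for v in ("C", "E", "R2", "R3"):
            assert rows.loc[v, "total_degree"] == 2

    def test_diamond_distribution(self, diamond_rc):
        report = degree_report(diamond_rc)
        assert report.distribution == pytest.approx(
            {2: 4 / 7, 3: 2 / 7, 6: 1 / 7}
        )

    def test_distribution_sums_to_one(self, random_models):
        for model in random_models:
            net = build_network(model, "RC")
            report = degree_report(net)
            assert sum(report.histogram.values()) == net.n_vertices
            assert math.isclose(sum(report.distribution.values()), 1.0,
                                abs_tol=1e-12)
            assert (report.rows.total_degree
                    == report.rows.in_degree + report.rows.out_degree).all()

    def test_single_isolated_vertex(self):
        net = MetabolicNetwork("CC")
        net.add_vertex("X", METABOLITE)
        report = degree_report(net)
        assert report.rows.iloc[0][["in_degree", "out_degree"]].tolist() == [0, 0]
        assert report.distribution == {0: 1.0}


class TestNeighbors:
    def test_diamond(self, diamond_rc):
        assert neighbors(diamond_rc, "E") == ({"R2"}, {"R3"})
        assert neighbors(diamond_rc, "R1") == ({"A", "B", "C"}, {"A", "B", "C"})

    def test_isolated(self):
        net = MetabolicNetwork("CC")
        net.add_vertex("X", METABOLITE)
        assert neighbors(net, "X") == (set(), set())

    def test_unknown(self, diamond_rc):
        with pytest.raises(VertexNotFoundError):
            neighbors(diamond_rc, "Z")


class TestShortestPath:
    def test_bfs_crosses_the_reversible_reaction(self, diamond_rc):
        result = shortest_path(diamond_rc, "A", "B", BFS)
        assert result.vertices == ["A", "R1", "B"]
        assert result.length == 2

    def test_sbbfs_takes_the_biochemical_detour(self, diamond_rc):
        result = shortest_path(diamond_rc, "A", "B", SBBFS)
        assert result.vertices == ["A", "R2", "E", "R3", "B"]
        assert result.length == 4

    def test_identity_path(self, diamond_rc):
        for mode in (BFS, SBBFS):
            result = shortest_path(diamond_rc, "A", "A", mode)
            assert result.vertices == ["A"] and result.length == 0

    def test_absent_when_unreachable(self):
        net = toy_path_network(("a", "b"))
        assert shortest_path(net, "b", "a") is None

    def test_lexicographic_tie_break(self):
        net = toy_path_network(("s", "b"), ("s", "a"), ("a", "t"), ("b", "t"))
        assert shortest_path(net, "s", "t").vertices == ["s", "a", "t"]

    def test_sbbfs_on_non_rc_warns_and_degrades(self, diamond_model):
        cc = build_network(diamond_model, "CC")
        with pytest.warns(UserWarning, match="degrades"):
            result = shortest_path(cc, "A", "B", SBBFS)
        assert result.length == 2  # plain BFS distance in CC

    def test_unknown_vertex(self, diamond_rc):
        with pytest.raises(VertexNotFoundError):
            shortest_path(diamond_rc, "A", "Z")


class TestSingleSourceDistances:
    def test_diamond_sbbfs(self, diamond_rc):
        dist = single_source_distances(diamond_rc, "A", SBBFS)
        assert dist["E"] == 2 and dist["B"] == 4 and dist["C"] == 2

    def test_diamond_bfs(self, diamond_rc):
        assert single_source_distances(diamond_rc, "A", BFS)["B"] == 2

    def test_source_without_out_edges(self):
        net = toy_path_network(("a", "b"))
        assert single_source_distances(net, "b") == {"b": 0}

    def test_sbbfs_matches_simple_path_oracle(self, random_models):
        """On >=100 (network, source) cases the constrained distances equal
        exhaustive enumeration of set-rule-respecting simple paths."""
        cases = 0
        for model in random_models:
            rc = build_network(model, "RC")
            assert rc.n_vertices <= 13
            for source in rc.vertices():
                expected = constrained_simple_path_distances(rc, source)
                assert single_source_distances(rc, source, SBBFS) == expected
                cases += 1
        assert cases >= 100

    def test_bfs_never_longer_than_sbbfs(self, random_models):
        for model in random_models:
            rc = build_network(model, "RC")
            for source in rc.vertices():
                plain = single_source_distances(rc, source, BFS)
                constrained = single_source_distances(rc, source, SBBFS)
                assert set(constrained) <= set(plain)
                for v, d in constrained.items():
                    assert plain[v] <= d

    def test_bfs_matches_oracle(self, random_models):
        for model in random_models[:10]:
            rc = build_network(model, "RC")
            for source in rc.vertices():
                assert single_source_distances(rc, source, BFS) == \
                    bfs_distances(rc, source)


class TestSbbfsPathValidity:
    def test_returned_paths_respect_the_set_rule(self, random_models):
        for model in random_models:
            rc = build_network(model, "RC")
            vertices = rc.vertices()
            for s in vertices:
                for t in vertices:
                    result = shortest_path(rc, s, t, SBBFS)
                    if result is not None:
                        assert path_respects_set_rule(rc, result.vertices), \
                            f"{result.vertices} violates the set-exit rule"


class TestGlobalPathMetrics:
    def test_directed_path(self):
        net = toy_path_network(("a", "b"), ("b", "c"))
        m = global_path_metrics(net)
        assert (m.diameter, m.connected_pair_count) == (2, 3)
        assert m.mean_shortest_path == pytest.approx(4 / 3)

    def test_complete_symmetric_digraph(self):
        edges = [(u, v) for u in "abc" for v in "abc" if u != v]
        m = global_path_metrics(toy_path_network(*edges))
        assert (m.diameter, m.mean_shortest_path, m.connected_pair_count) == (1, 1.0, 6)

    def test_no_connected_pairs(self):
        net = MetabolicNetwork("CC")
        net.add_vertex("x", METABOLITE)
        net.add_vertex("y", METABOLITE)
        m = global_path_metrics(net)
        assert (m.diameter, m.mean_shortest_path, m.connected_pair_count) == (0, 0.0, 0)

    def test_diamond_matches_all_pairs_oracle(self, diamond_rc):
        pairs = 0
        total = 0
        diameter = 0
        for s in diamond_rc.vertices():
            for t, d in bfs_distances(diamond_rc, s).items():
                if t != s:
                    pairs += 1
                    total += d
                    diameter = max(diameter, d)
        m = global_path_metrics(diamond_rc, BFS)
        assert (m.diameter, m.connected_pair_count) == (diameter, pairs)
        assert m.mean_shortest_path == pytest.approx(total / pairs)


class TestRankings:
    def test_degree_top_vertex(self, diamond_rc):
        result = rank_vertices(diamond_rc, "DEGREE")
        assert result.ordering[0] == "R1"
        assert result.scores["R1"] == 6

    def test_betweenness_single_intermediate(self):
        net = toy_path_network(("a", "b"), ("b", "c"))
        scores = rank_vertices(net, "BETWEENNESS").scores
        assert scores == {"a": 0.0, "b": 1.0, "c": 0.0}

    def test_closeness_formula(self):
        net = toy_path_network(("a", "b"), ("b", "c"))
        scores = rank_vertices(net, "CLOSENESS").scores
        assert scores["a"] == pytest.approx(2 / 3)
        assert scores["c"] == 0.0

    def test_hits_star(self):
        net = toy_path_network(("h", "a1"), ("h", "a2"), ("h", "a3"))
        result = rank_vertices(net, "HITS", by_hub=True)
        assert result.ordering[0] == "h"
        auth = result.authority_scores
        assert auth["a1"] == pytest.approx(auth["a2"]) == pytest.approx(auth["a3"])
        assert auth["h"] == pytest.approx(0.0, abs=1e-9)

    def test_betweenness_matches_brute_force(self, random_models):
        for model in random_models[:15]:
            net = build_network(model, "RC")
            if net.n_vertices > 10:
                continue
            expected = brute_betweenness(net.simple_digraph())
            got = rank_vertices(net, "BETWEENNESS").scores
            for v in expected:
                assert got[v] == pytest.approx(expected[v], abs=1e-9)

    def test_closeness_matches_brute_force(self, random_models):
        for model in random_models[:15]:
            net = build_network(model, "RC")
            expected = brute_closeness(net.simple_digraph())
            got = rank_vertices(net, "CLOSENESS").scores
            for v in expected:
                assert got[v] == pytest.approx(expected[v], abs=1e-12)

    def test_hits_matches_dense_eigendecomposition(self, random_models):
        checked = 0
        for model in random_models[:15]:
            net = build_network(model, "RC")
            expected = hits_authority_eig(net)
            if expected is None:  # degenerate spectrum: vector not unique
                continue
            checked += 1
            got = rank_vertices(net, "HITS").authority_scores
            for v in expected:
                assert got[v] == pytest.approx(expected[v], abs=1e-6)
        assert checked >= 5

    def test_scores_finite_nonnegative_ordering_permutation(self, diamond_rc):
        for method in ("DEGREE", "BETWEENNESS", "CLOSENESS", "HITS"):
            result = rank_vertices(diamond_rc, method)
            assert sorted(result.ordering) == diamond_rc.vertices()
            assert all(math.isfinite(s) and s >= 0 for s in result.scores.values())

    def test_unknown_method(self, diamond_rc):
        with pytest.raises(UsageError):
            rank_vertices(diamond_rc, "PAGERANK")
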