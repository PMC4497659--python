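import itertools
import re

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from autocmap import (count_spanning_trees, export_graph, h_function,
                      kruskal_mst, load_edge_list, maximally_regular_graph,
                      pruning_trace, tree_center)
from conftest import random_distance_matrix


def frame_from(pairs, names):
    d = pd.DataFrame(0.0, index=names, columns=names)
    for (a, b), w in pairs.items():
        d.loc[a, b] = d.loc[b, a] = w
    return d


def brute_force_mst_weight(frame):
    """Minimum total weight over all spanning trees, by enumerating every
    (n-1)-edge subset of the complete graph."""
    names = list(frame.columns)
    n = len(names)
    all_edges = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    best = np.inf
    n_trees = 0
    for subset in itertools.combinations(all_edges, n - 1):
        g = nx.Graph(subset)
        if g.number_of_nodes() == n and nx.is_connected(g):
            n_trees += 1
            best = min(best, sum(frame.loc[a, b] for a, b in subset))
    return best, n_trees


def star(n_leaves):
    g = nx.Graph()
    g.add_edges_from(("hub", f"l{i}") for i in range(n_leaves))
    return g


def chain(n):
    return nx.path_graph([f"c{i}" for i in range(n)])


class TestKruskal:
    def test_three_node_hand_example(self):
        d = frame_from({("a", "b"): 1, ("a", "c"): 2, ("b", "c"): 3},
                       ["a", "b", "c"])
        tree, skipped = kruskal_mst(d)
        assert set(map(frozenset, tree.edges)) == {frozenset("ab"), frozenset("ac")}
        assert tree.graph["total_weight"] == 3
        assert skipped == [("b", "c", 3.0)]

    @pytest.mark.parametrize("n", [3, 4, 5, 6])
    def test_matches_exhaustive_minimum(self, n):
        rng = np.random.default_rng(n)
        frame = random_distance_matrix(rng, n)
        tree, skipped = kruskal_mst(frame)
        best, n_trees = brute_force_mst_weight(frame)
        assert tree.graph["total_weight"] == pytest.approx(best)
        assert n_trees == count_spanning_trees(n)
        # complete graph feeds V(V-1)/2 edges in total
        assert tree.number_of_edges() + len(skipped) == n * (n - 1) // 2

    def test_agrees_with_networkx(self):
        rng = np.random.default_rng(99)
        frame = random_distance_matrix(rng, 12)
        tree, _ = kruskal_mst(frame)
        g = nx.from_pandas_adjacency(frame)
        ref = nx.minimum_spanning_tree(g, algorithm="kruskal")
        assert tree.graph["total_weight"] == pytest.approx(
            ref.size(weight="weight"))

    def test_equal_distances_resolve_lexicographically(self):
        names = ["a", "b", "c", "d"]
        d = pd.DataFrame(1.0, index=names, columns=names)
        np.fill_diagonal(d.values, 0.0)
        tree, _ = kruskal_mst(d)
        assert sorted(tree.edges) == [("a", "b"), ("a", "c"), ("a", "d")]

    def test_monotone_transform_keeps_topology(self):
        rng = np.random.default_rng(17)
        frame = random_distance_matrix(rng, 8)
        t1, _ = kruskal_mst(frame)
        t2, _ = kruskal_mst(frame**2)  # strictly monotone on positive entries
        assert set(map(frozenset, t1.edges)) == set(map(frozenset, t2.edges))

    def test_asymmetric_input_rejected(self):
        d = pd.DataFrame([[0, 1.0], [2.0, 0]], index=list("ab"), columns=list("ab"))
        with pytest.raises(ValueError):
            kruskal_mst(d)


class TestSpanningTreeCount:
    @pytest.mark.parametrize("v,expected", [(2, 1), (3, 3), (6, 1296)])
    def test_cayley_values(self, v, expected):
        assert count_spanning_trees(v) == expected

    def test_matches_matrix_tree_theorem(self):
        # independent oracle: Kirchhoff determinant on the complete graph
        for v in range(2, 9):
            lap = v * np.eye(v) - np.ones((v, v))
            cofactor = round(float(np.linalg.det(lap[1:, 1:])))
            assert count_spanning_trees(v) == cofactor

    def test_rejects_tiny_graphs(self):
        with pytest.raises(ValueError):
            count_spanning_trees(1)


class TestPruning:
    def test_star_hand_trace(self):
        trace = pruning_trace(star(4))
        assert trace.removed_per_cycle == [4, 1]
        assert trace.cycles == 2
        assert trace.mu == pytest.approx(2.5)
        assert trace.phi == pytest.approx(2.5)

    def test_chain_hand_trace(self):
        trace = pruning_trace(chain(5))
        assert trace.removed_per_cycle == [2, 2, 1]
        assert trace.mu == pytest.approx(5 / 3)
        assert trace.phi == pytest.approx(1.5)

    def test_single_edge(self):
        trace = pruning_trace(nx.Graph([("a", "b")]))
        assert trace.removed_per_cycle == [2]
        assert trace.mu == pytest.approx(2.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_trees_prune_completely(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 30))
        tree = nx.random_labeled_tree(n, seed=int(rng.integers(2**31)))
        trace = pruning_trace(tree)
        assert trace.removed_total == n
        assert trace.core_size == 0

    def test_two_core_survives(self):
        g = nx.cycle_graph(4)
        g.add_edge(0, "tail")
        trace = pruning_trace(g)
        assert trace.removed_per_cycle == [1]
        assert trace.core_size == 4

    def test_disconnected_components_prune_in_parallel(self):
        g = nx.union(star(3), chain(3))
        with pytest.warns(UserWarning):
            trace = pruning_trace(g)
        assert trace.removed_total == g.number_of_nodes()


class TestHFunction:
    def test_star_value(self):
        assert h_function(star(4)).h == pytest.approx(0.9375)

    def test_chain_value(self):
        assert h_function(chain(5)).h == pytest.approx((5 / 3) * 0.5 / 4, abs=1e-6)

    @pytest.mark.parametrize("n", range(5, 13))
    def test_star_more_hub_oriented_than_chain(self, n):
        assert h_function(star(n - 1)).h > h_function(chain(n)).h

    @pytest.mark.parametrize("seed", range(8))
    def test_bounded_on_random_trees(self, seed):
        tree = nx.random_labeled_tree(12, seed=seed)
        h = h_function(tree).h
        assert 0 < h < 2

    def test_leafless_graph_scores_zero(self):
        assert h_function(nx.complete_graph(6)).h == 0.0
        assert h_function(nx.cycle_graph(5)).h == 0.0


class TestMRG:
    def test_two_nodes_have_no_mrg(self):
        d = frame_from({("a", "b"): 1.0}, ["a", "b"])
        res = maximally_regular_graph(d)
        assert not res.has_mrg
        assert res.r_star == 0 and res.r == 0
        assert set(res.graph.edges) == set(res.mst.edges)

    @pytest.mark.parametrize("seed", range(6))
    def test_h_star_dominates_h0_and_edge_count(self, seed):
        rng = np.random.default_rng(seed)
        frame = random_distance_matrix(rng, 9)
        res = maximally_regular_graph(frame)
        assert res.h_star >= res.h0
        assert res.graph.number_of_edges() == len(frame) - 1 + res.r_star
        assert res.r <= (len(frame) - 1) * (len(frame) - 2) // 2
        # candidate list never contains an MST edge
        mst_edges = set(map(frozenset, res.mst.edges))
        assert all(frozenset((a, b)) not in mst_edges for a, b, _ in res.skipped)

    def test_four_node_curve_matches_exhaustive_walk(self):
        d = frame_from({("a", "b"): 1.0, ("a", "c"): 1.1, ("a", "d"): 1.2,
                        ("b", "c"): 1.3, ("b", "d"): 2.0, ("c", "d"): 2.1},
                       ["a", "b", "c", "d"])
        res = maximally_regular_graph(d)
        # replay: add skipped edges one at a time, score each graph afresh
        g = res.mst.copy()
        curve = [h_function(g).h]
        for u, v, w in res.skipped:
            g.add_edge(u, v, weight=w)
            curve.append(h_function(g).h)
        assert res.h_curve == pytest.approx(curve)
        assert res.r_star == int(np.argmax(curve))
        # star MST on 4 nodes: adding any chord can only reduce hubness
        assert res.r_star == 0 and res.h0 == pytest.approx(h_function(star(3)).h)

    def test_tie_resolves_to_fewest_added_edges(self):
        rng = np.random.default_rng(11)
        frame = random_distance_matrix(rng, 7)
        res = maximally_regular_graph(frame)
        first_max = next(i for i, h in enumerate(res.h_curve)
                         if h == max(res.h_curve))
        assert res.r_star == first_max


class TestExport:
    def test_edge_list_round_trip(self, tmp_path):
        rng = np.random.default_rng(1)
        tree, _ = kruskal_mst(random_distance_matrix(rng, 6))
        path = export_graph(tree, tmp_path / "t.csv")
        back = load_edge_list(path)
        assert set(map(frozenset, back.edges)) == set(map(frozenset, tree.edges))
        for u, v, data in tree.edges(data=True):
            assert back.edges[u, v]["weight"] == data["weight"]

    def test_graphml_preserves_weights(self, tmp_path):
        tree = nx.Graph()
        tree.add_edge("a", "b", weight=0.25)
        path = export_graph(tree, tmp_path / "t.graphml", fmt="graphml")
        back = nx.read_graphml(path)
        assert back.edges["a", "b"]["weight"] == 0.25

    def test_dot_output_is_wellformed(self, tmp_path):
        tree = nx.Graph()
        tree.add_edge("a", "b", weight=0.5)
        text = export_graph(tree, tmp_path / "t.dot", fmt="dot").read_text()
        assert text.startswith("graph G {") and text.rstrip().endswith("}")
        assert re.search(r'"a" -- "b" \[weight=0\.5\];', text)

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            export_graph(nx.Graph([("a", "b")]), tmp_path / "x", fmt="svg")


class TestTreeCenter:
    def test_star_center_is_hub(self):
        assert tree_center(star(5)) == "hub"

    def test_degree_tie_broken_by_eccentricity(self):
        # path a-b-c-d-e: b, c, d all have degree 2; c is innermost
        assert tree_center(chain(5)) == "c2"
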