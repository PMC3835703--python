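import math

import numpy as np
import pytest

from net3d.errors import GraphLookupError, NumericError, ParameterError
from net3d.fixtures import random_graph
from net3d.graph import Graph
from net3d.layout import (CoarseningLevel, LayoutParams, coarsen,
                          compute_displacements, fr_layout, layout_quality,
                          multilevel_layout, prolong)

from _oracles import brute_force_displacements
from conftest import ring


def pair_graph() -> Graph:
    g = Graph()
    g.add_edge("a", "b")
    return g


def dist(p, q):
    return math.dist(p, q)


class TestForceSweep:
    def test_single_node_zero_displacement(self):
        d = compute_displacements({"a": (1.0, 2.0, 3.0)}, [], LayoutParams())
        assert d["a"] == (0.0, 0.0, 0.0)

    def test_isolated_pair_repulsion_closed_form(self):
        # two free nodes at distance 2k repel with magnitude k^2/(2k) = k/2
        k = 1.0
        d = compute_displacements({"a": (0.0, 0.0, 0.0), "b": (2 * k, 0.0, 0.0)},
                                  [], LayoutParams())
        assert d["a"][0] == pytest.approx(-k / 2, abs=1e-12)
        assert d["b"][0] == pytest.approx(+k / 2, abs=1e-12)
        assert d.evaluations == 1

    def test_connected_pair_equilibrium_at_k(self):
        # attraction d^2/k and repulsion k^2/d cancel exactly at d = k
        k = 1.0
        d = compute_displacements({"a": (0.0, 0.0, 0.0), "b": (k, 0.0, 0.0)},
                                  [("a", "b")], LayoutParams())
        assert np.allclose(d["a"], 0.0, atol=1e-12)
        assert np.allclose(d["b"], 0.0, atol=1e-12)

    def test_temperature_caps_displacement_norm(self):
        d = compute_displacements({"a": (0.0, 0.0, 0.0), "b": (0.1, 0.0, 0.0)},
                                  [], LayoutParams(), temperature=0.05)
        assert np.linalg.norm(d["a"]) == pytest.approx(0.05)

    def test_non_finite_coordinate_names_the_node(self):
        with pytest.raises(NumericError, match="bad"):
            compute_displacements({"bad": (math.nan, 0.0, 0.0)}, [], LayoutParams())

    def test_missing_endpoint_is_an_error(self):
        with pytest.raises(GraphLookupError):
            compute_displacements({"a": (0, 0, 0)}, [("a", "ghost")], LayoutParams())

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_brute_force_double_loop(self, seed):
        """All-pairs sweep equals an explicit O(n^2) loop to 1e-9/coordinate."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 13))
        g = random_graph(n, min(n, n * (n - 1) // 2), seed=seed)
        positions = {nid: tuple(rng.uniform(-2, 2, 3)) for nid in g.node_ids()}
        edges = [(e.source, e.target) for e in g.edges()]
        ours = compute_displacements(positions, edges, LayoutParams())
        oracle = brute_force_displacements(positions, edges, k=1.0)
        for nid in positions:
            assert np.allclose(ours[nid], oracle[nid], atol=1e-9)


class TestSingleLevelLayout:
    def test_single_node_at_origin(self):
        g = Graph()
        g.add_node("only")
        st = fr_layout(g, LayoutParams(seed=5))
        assert np.allclose(st.positions["only"], 0.0)

    def test_empty_graph_rejected(self):
        with pytest.raises(ParameterError):
            fr_layout(Graph())

    @pytest.mark.parametrize("seed", range(5))
    def test_connected_pair_converges_to_k(self, seed):
        st = fr_layout(pair_graph(), LayoutParams(seed=seed))
        d = dist(st.positions["a"], st.positions["b"])
        assert abs(d - 1.0) / 1.0 < 0.05

    @pytest.mark.parametrize("seed", range(5))
    def test_triangle_equilateral(self, triangle, seed):
        st = fr_layout(triangle, LayoutParams(seed=seed))
        q = layout_quality(triangle, st)
        assert q["edge_length_cv"] < 0.05

    def test_bit_for_bit_determinism(self):
        g = random_graph(30, 60, seed=9)
        a = fr_layout(g, LayoutParams(seed=42))
        b = fr_layout(g, LayoutParams(seed=42))
        assert a.positions == b.positions

    def test_different_seed_different_layout(self):
        g = random_graph(30, 60, seed=9)
        a = fr_layout(g, LayoutParams(seed=1))
        b = fr_layout(g, LayoutParams(seed=2))
        assert a.positions != b.positions


class TestCoarsening:
    def test_single_match_collapses_pair(self):
        lvl = coarsen(pair_graph())
        assert lvl.coarse_graph.n_nodes == 1 and lvl.coarse_graph.n_edges == 0
        assert lvl.parent_map == {"a": "a", "b": "a"}

    def test_path_with_sorted_order(self, path4):
        lvl = coarsen(path4)  # deterministic id-sorted edge order
        assert set(lvl.parent_map.values()) == {"a", "c"}
        assert lvl.coarse_graph.n_edges == 1
        assert lvl.coarse_graph.edge("a", "c", "coarse").attributes["weight"] == 1.0

    def test_triangle_merges_parallel_edges_no_self_loop(self, triangle):
        lvl = coarsen(triangle)
        cg = lvl.coarse_graph
        assert cg.n_nodes == 2 and cg.n_edges == 1
        (edge,) = list(cg.edges())
        assert edge.source != edge.target
        assert edge.attributes["weight"] == 2.0

    def test_too_small_graph_rejected(self):
        g = Graph()
        g.add_node("x")
        with pytest.raises(ParameterError):
            coarsen(g)

    @pytest.mark.parametrize("seed", [0, 3, 11])
    def test_progress_and_connectivity_preserved(self, seed):
        import networkx as nx

        g = ring(16)  # connected, every node matchable
        while g.n_nodes > 1:
            lvl = coarsen(g, seed=seed)
            assert lvl.coarse_graph.n_nodes < g.n_nodes
            assert set(lvl.parent_map) == set(g.node_ids())
            assert set(lvl.parent_map.values()) == set(lvl.coarse_graph.node_ids())
            if lvl.coarse_graph.n_nodes > 1:
                assert nx.is_connected(lvl.coarse_graph.to_networkx())
            g = lvl.coarse_graph


class TestProlongation:
    def test_children_stay_within_jitter_radius(self):
        lvl = coarsen(pair_graph())
        pos = prolong(lvl, {"a": (1.0, 1.0, 1.0)}, jitter_radius=0.25)
        for child in ("a", "b"):
            assert dist(pos[child], (1.0, 1.0, 1.0)) <= 0.25
        assert dist(pos["a"], pos["b"]) <= 0.5  # triangle inequality
        assert pos["a"] != pos["b"]

    def test_all_fine_nodes_covered(self, path4):
        lvl = coarsen(path4)
        coarse_pos = {nid: (0.0, 0.0, 0.0) for nid in lvl.coarse_graph.node_ids()}
        pos = prolong(lvl, coarse_pos, jitter_radius=0.1)
        assert set(pos) == set(path4.node_ids())

    def test_missing_parent_position_is_an_error(self):
        lvl = CoarseningLevel(coarse_graph=Graph(), parent_map={"a": "ghost"})
        with pytest.raises(GraphLookupError):
            prolong(lvl, {}, jitter_radius=0.1)


class TestMultilevel:
    def test_small_graph_identical_to_single_level(self, triangle):
        params = LayoutParams(seed=3)
        assert multilevel_layout(triangle, params).positions == \
            fr_layout(triangle, params).positions

    @pytest.mark.parametrize("seed", range(5))
    def test_ring_edge_lengths_uniform(self, seed):
        g = ring(20)
        st = multilevel_layout(g, LayoutParams(seed=seed))
        assert layout_quality(g, st)["edge_length_cv"] < 0.15

    def test_deterministic_across_runs(self):
        g = random_graph(120, 300, seed=4)
        a = multilevel_layout(g, LayoutParams(seed=7))
        b = multilevel_layout(g, LayoutParams(seed=7))
        assert a.positions == b.positions

    def test_neighborhood_mode_bounds_per_iteration_evaluations(self):
        g = random_graph(2000, 8000, seed=2)
        st = multilevel_layout(g, LayoutParams(seed=2))
        assert st.max_evals_per_iteration <= 50 * 2000
        assert all(math.isfinite(c) for p in st.positions.values() for c in p)


class TestQualityMetrics:
    def test_pair_at_distance_k(self):
        g = pair_graph()
        q = layout_quality(g, {"a": (0.0, 0.0, 0.0), "b": (1.0, 0.0, 0.0)})
        assert q["edge_length_mean"] == pytest.approx(1.0)
        assert q["edge_length_cv"] == pytest.approx(0.0)

    def test_equilateral_triangle_cv_zero(self, triangle):
        h = math.sqrt(3) / 2
        pos = {"a": (0.0, 0.0, 0.0), "b": (1.0, 0.0, 0.0), "c": (0.5, h, 0.0)}
        assert layout_quality(triangle, pos)["edge_length_cv"] == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_layout_min_separation_zero(self, triangle):
        pos = {n: (0.0, 0.0, 0.0) for n in triangle.node_ids()}
        assert layout_quality(triangle, pos)["min_separation"] == 0.0
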