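import pytest
from hypothesis import given, settings, strategies as st

from net3d.dynamics import (animate, apply_graph_events, build_motion_network,
                            diff_graphs, filter_positive, map_values_to_color,
                            map_values_to_size, map_values_to_thickness,
                            split_by_attribute)
from net3d.errors import ConfigError, NumericError
from net3d.fixtures import random_graph, synthetic_frames, synthetic_timecourse
from net3d.graph import COLOR_SCHEMES, Graph, VisualStyle
from net3d.io import AttributeTable
from net3d.layout import LayoutParams, multilevel_layout


class TestValueMapping:
    def test_affine_endpoints(self):
        style = VisualStyle(size_range=(10.0, 40.0))
        assert map_values_to_size({"a": 0.0, "b": 1.0}, style) == {"a": 10.0, "b": 40.0}

    def test_constant_maps_to_midpoint(self):
        style = VisualStyle(size_range=(10.0, 40.0))
        assert map_values_to_size({"a": 5.0, "b": 5.0}, style) == {"a": 25.0, "b": 25.0}

    def test_linearity(self):
        style = VisualStyle(size_range=(0.001, 1.0))
        style = VisualStyle(size_range=(0.5, 1.0))
        out = map_values_to_size({"a": 0.0, "b": 2.0, "c": 4.0}, style)
        assert out["b"] == pytest.approx((out["a"] + out["c"]) / 2)

    def test_thickness_same_contract(self):
        style = VisualStyle(thickness_range=(1.0, 9.0))
        out = map_values_to_thickness({"e1": 0.0, "e2": 1.0}, style)
        assert out == {"e1": 1.0, "e2": 9.0}

    def test_non_finite_value_names_element(self):
        with pytest.raises(NumericError, match="bad"):
            map_values_to_size({"bad": float("nan")}, VisualStyle())

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=8, unique=True))
    def test_order_preserved(self, values):
        mapped = map_values_to_size({f"v{i}": v for i, v in enumerate(values)},
                                    VisualStyle(size_range=(1.0, 2.0)))
        order = sorted(range(len(values)), key=lambda i: values[i])
        sizes = [mapped[f"v{i}"] for i in order]
        assert all(a <= b for a, b in zip(sizes, sizes[1:]))

    def test_color_ramp_endpoints_and_midpoint(self):
        lo, mid, hi = COLOR_SCHEMES["heatmap"]
        out = map_values_to_color({"a": 0.0, "b": 5.0, "c": 10.0}, "heatmap")
        assert out["a"] == lo and out["c"] == hi
        assert out["b"] == pytest.approx(mid)

    def test_unknown_scheme_is_a_config_error(self):
        with pytest.raises(ConfigError, match="nope"):
            map_values_to_color({"a": 1.0}, "nope")


def flux_graph():
    g = Graph()
    g.add_edge("M1", "M2", "rx")  # edge id "M1 (rx) M2"
    g.add_edge("M2", "M3", "rx")
    return g


class TestFluxFilter:
    def test_zero_flux_edges_removed(self):
        g = flux_graph()
        table = AttributeTable("Flux", {"M1 (rx) M2": 2.5, "M2 (rx) M3": 0.0}, "number")
        out = filter_positive(g, table)
        assert out.n_edges == 1 and out.has_edge("M1", "M2", "rx")
        assert not out.has_node("M3")  # orphaned with no positive value

    def test_all_zero_leaves_empty_edge_set(self):
        table = AttributeTable("Flux", {"M1 (rx) M2": 0.0, "M2 (rx) M3": 0.0}, "number")
        assert filter_positive(flux_graph(), table).n_edges == 0

    def test_threshold_is_strict(self):
        table = AttributeTable("Flux", {"M1 (rx) M2": 2.5, "M2 (rx) M3": 5.0}, "number")
        out = filter_positive(flux_graph(), table, threshold=3.0)
        assert [e.id for e in out.edges()] == ["M2 (rx) M3"]

    def test_missing_elements_count_as_zero(self):
        table = AttributeTable("Flux", {"M1 (rx) M2": 1.0}, "number")
        out = filter_positive(flux_graph(), table)
        assert out.n_edges == 1

    def test_keep_orphans_flag(self):
        table = AttributeTable("Flux", {"M1 (rx) M2": 1.0}, "number")
        out = filter_positive(flux_graph(), table, keep_orphans=True)
        assert out.has_node("M3")

    def test_node_table_filters_nodes(self):
        g = flux_graph()
        table = AttributeTable("Rate", {"M1": 1.0, "M2": 2.0, "M3": 0.0}, "number")
        out = filter_positive(g, table)
        assert set(out.node_ids()) == {"M1", "M2"} and out.n_edges == 1

    def test_text_table_rejected(self):
        with pytest.raises(ConfigError):
            filter_positive(flux_graph(), AttributeTable("F", {"a": "x"}, "text"))


class TestSplit:
    def test_six_condition_split(self):
        g = Graph()
        table = AttributeTable("Filename", {}, "text")
        for i in range(6):
            a, b = f"c{i}a", f"c{i}b"
            g.add_edge(a, b)
            table.entries[a] = table.entries[b] = f"cond{i}"
        parts = split_by_attribute(g, table)
        assert len(parts) == 6
        assert [v for v, _ in parts] == sorted(f"cond{i}" for i in range(6))
        assert all(sub.n_edges == 1 for _, sub in parts)

    def test_single_value_returns_whole_graph(self):
        g = random_graph(8, 10, seed=1)
        table = AttributeTable("F", {n: "all" for n in g.node_ids()}, "text")
        [(value, sub)] = split_by_attribute(g, table)
        assert value == "all" and sub.same_topology(g)

    def test_cross_group_edges_dropped(self):
        g = Graph()
        g.add_edge("a", "b")
        table = AttributeTable("F", {"a": "x", "b": "y"}, "text")
        parts = split_by_attribute(g, table)
        assert all(sub.n_edges == 0 for _, sub in parts)

    def test_unlabelled_nodes_form_unassigned_group(self):
        g = Graph()
        g.add_node("a")
        g.add_node("b")
        parts = split_by_attribute(g, AttributeTable("F", {"a": "x"}, "text"))
        assert parts[-1][0] == "unassigned"
        assert parts[-1][1].node_ids() == ["b"]

    @pytest.mark.parametrize("seed", [0, 5])
    def test_groups_partition_the_node_set(self, seed):
        import numpy as np

        g = random_graph(20, 35, seed=seed)
        rng = np.random.default_rng(seed)
        table = AttributeTable("F", {n: f"g{rng.integers(0, 4)}" for n in g.node_ids()},
                               "text")
        parts = split_by_attribute(g, table)
        seen: list[str] = []
        for _, sub in parts:
            seen.extend(sub.node_ids())
        assert sorted(seen) == sorted(g.node_ids())  # disjoint cover


def graph_of(nodes, edges=()):
    g = Graph()
    for n in nodes:
        g.add_node(n)
    for a, b in edges:
        g.add_edge(a, b)
    return g


class TestMotionNetwork:
    def test_identical_frames_have_empty_second_event_list(self):
        f = graph_of("AB", [("A", "B")])
        motion = build_motion_network([f, f.copy()], ["t1", "t2"])
        assert motion.events[1] == []

    def test_set_difference_events(self):
        m = build_motion_network([graph_of("AB"), graph_of("BC")], ["t1", "t2"])
        kinds = [(e.kind, e.payload["id"]) for e in m.events[1]]
        assert kinds == [("delete", "A"), ("insert", "C")]

    def test_node_absent_in_middle_frame_is_reinserted(self):
        frames = [graph_of("AX"), graph_of("A"), graph_of("AX")]
        m = build_motion_network(frames, ["t1", "t2", "t3"])
        assert [(e.kind, e.payload["id"]) for e in m.events[1]] == [("delete", "X")]
        assert [(e.kind, e.payload["id"]) for e in m.events[2]] == [("insert", "X")]

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ConfigError):
            build_motion_network([graph_of("A"), graph_of("A")], ["t", "t"])

    def test_deletions_precede_insertions_edges_outermost(self):
        old = graph_of("AB", [("A", "B")])
        new = graph_of("BC", [("B", "C")])
        events = diff_graphs(old, new)
        order = [(e.kind, e.target) for e in events]
        assert order == [("delete", "edge"), ("delete", "node"),
                         ("insert", "node"), ("insert", "edge")]

    def test_replay_reproduces_every_frame_exactly(self):
        base = random_graph(15, 25, seed=3)
        frames = synthetic_frames(base, 5, churn=0.4, seed=3)
        m = build_motion_network(frames, [f"t{i}" for i in range(5)])
        for t, frame in enumerate(frames):
            assert m.replay(t) == frame

    def test_union_graph_is_union_of_replayed_frames(self):
        base = random_graph(12, 18, seed=8)
        frames = synthetic_frames(base, 4, churn=0.5, seed=8)
        m = build_motion_network(frames, list("abcd"))
        union_nodes = set()
        union_edges = set()
        for frame in m.frames():
            union_nodes |= set(frame.node_ids())
            union_edges |= set(frame.edge_keys())
        assert union_nodes == set(m.union_graph.node_ids())
        assert union_edges == set(m.union_graph.edge_keys())

    def test_insert_of_existing_node_rejected_on_replay(self):
        from net3d.dynamics import MutationEvent

        g = graph_of("A")
        with pytest.raises(ConfigError):
            apply_graph_events(g, [MutationEvent(0, "insert", "node", {"id": "A"})])


class TestAnimate:
    def _motion_and_layout(self, n_frames, churn, seed):
        base = random_graph(12, 20, seed=seed)
        frames = synthetic_frames(base, n_frames, churn=churn, seed=seed)
        motion = build_motion_network(frames, [f"t{i}" for i in range(n_frames)])
        layout = multilevel_layout(motion.union_graph, LayoutParams(seed=seed))
        return motion, layout, frames

    def test_single_frame_equals_static_render(self):
        motion, layout, frames = self._motion_and_layout(1, 0.0, 1)
        [scene] = animate(motion, layout)
        assert scene.graph == frames[0]
        assert scene.positions == {n: layout.positions[n] for n in frames[0].node_ids()}

    def test_shared_nodes_share_coordinates_across_frames(self):
        motion, layout, _ = self._motion_and_layout(3, 0.3, 2)
        scenes = animate(motion, layout)
        assert len(scenes) == 3
        for scene in scenes:
            for nid, p in scene.positions.items():
                assert p == layout.positions[nid]

    def test_six_condition_animation_matches_input_frames(self):
        motion, layout, frames = self._motion_and_layout(6, 0.4, 7)
        scenes = animate(motion, layout)
        assert len(scenes) == 6
        for scene, frame in zip(scenes, frames):
            assert set(scene.graph.node_ids()) == set(frame.node_ids())
            assert set(scene.graph.edge_keys()) == set(frame.edge_keys())

    def test_timeseries_drives_node_sizes(self):
        motion, layout, frames = self._motion_and_layout(4, 0.0, 3)
        ts = synthetic_timecourse(motion.union_graph, 4, seed=3)
        scenes = animate(motion, layout, timeseries=ts, channel="size")
        style = VisualStyle()
        for scene in scenes:
            assert set(scene.node_size) == set(scene.graph.node_ids())
            for size in scene.node_size.values():
                assert style.size_range[0] <= size <= style.size_range[1]

    def test_frame_count_mismatch_rejected(self):
        motion, layout, _ = self._motion_and_layout(3, 0.2, 4)
        ts = synthetic_timecourse(motion.union_graph, 2, seed=4)
        with pytest.raises(ConfigError):
            animate(motion, layout, timeseries=ts)
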