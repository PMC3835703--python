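"""Time-course visual mapping, flux filtering, condition splitting, and
motion networks.

A *motion network* is an ordered sequence of condition or time-point graphs
(frames) over a shared union graph.  Per-frame topology changes are stored
as ordered mutation events (deletions before insertions, each id-sorted)
such that replaying events 0..t from the empty graph reproduces frame t
exactly.  Animating a motion network keeps a single layout of the union
graph fixed across frames: elements absent from a frame are hidden, never
moved, which keeps topological change readable.

Numeric data (expression, metabolic flux, spectral counts) map onto visual
channels by affine interpolation: values span the style's size or thickness
range, and colors interpolate across a three-anchor ramp (min / mid / max of
the value range) such as the blue-black-yellow expression heat map.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import ConfigError, GraphLookupError, NumericError
from .graph import (COLOR_SCHEMES, Color, Graph, Scene, VisualStyle, edge_id)
from .io import AttributeTable, TimeSeriesTable
from .layout import LayoutState


# ------------------------------------------------------------------
# value → visual channel mapping


def _affine(values: dict[str, float], lo: float, hi: float) -> dict[str, float]:
    for key, v in values.items():
        if not math.isfinite(v):
            raise NumericError(f"non-finite value for element {key!r}")
    if not values:
        return {}
    vmin, vmax = min(values.values()), max(values.values())
    if vmax == vmin:
        mid = (lo + hi) / 2.0
        return {k: mid for k in values}
    scale = (hi - lo) / (vmax - vmin)
    return {k: lo + (v - vmin) * scale for k, v in values.items()}


def map_values_to_size(values: dict[str, float], style: VisualStyle) -> dict[str, float]:
    """Affine map of the value range onto ``style.size_range``; a constant
    input maps everything to the midpoint."""
    return _affine(values, *style.size_range)


def map_values_to_thickness(values: dict[str, float], style: VisualStyle) -> dict[str, float]:
    """Same contract as :func:`map_values_to_size`, onto the edge-thickness
    range."""
    return _affine(values, *style.thickness_range)


def map_values_to_color(values: dict[str, float], scheme: str = "heatmap") -> dict[str, Color]:
    """Linear interpolation across a named three-anchor ramp.

    The ramp anchors sit at the minimum, midpoint and maximum of the value
    range; a constant input maps to the middle anchor.
    """
    if scheme not in COLOR_SCHEMES:
        raise ConfigError(f"unknown color scheme {scheme!r}; known: {sorted(COLOR_SCHEMES)}")
    lo_c, mid_c, hi_c = COLOR_SCHEMES[scheme]
    for key, v in values.items():
        if not math.isfinite(v):
            raise NumericError(f"non-finite value for element {key!r}")
    if not values:
        return {}
    vmin, vmax = min(values.values()), max(values.values())
    out: dict[str, Color] = {}
    for key, v in values.items():
        if vmax == vmin:
            out[key] = mid_c
            continue
        t = (v - vmin) / (vmax - vmin)
        if t <= 0.5:
            a, b, u = lo_c, mid_c, t * 2.0
        else:
            a, b, u = mid_c, hi_c, (t - 0.5) * 2.0
        out[key] = tuple(a[i] + (b[i] - a[i]) * u for i in range(3))  # type: ignore[assignment]
    return out


# ------------------------------------------------------------------
# filtering and splitting


def filter_positive(graph: Graph, table: AttributeTable, threshold: float = 0.0,
                    keep_orphans: bool = False) -> Graph:
    """Keep only elements whose table value is strictly above ``threshold``.

    Used to de-clutter flux networks ("show only relationships with flux
    greater than zero").  The table may address edges (by ``"A (i) B"`` id)
    or nodes.  Elements missing from the table count as 0 and are dropped.
    Nodes orphaned by edge removal are kept only if they carry a positive
    node value or ``keep_orphans`` is set.
    """
    if table.value_kind != "number":
        raise ConfigError(f"filter_positive needs a numeric table, got {table.value_kind!r}")
    edge_ids = {e.id for e in graph.edges()}
    addresses_edges = any(k in edge_ids for k in table.entries)

    out = Graph(directed=graph.directed)
    if addresses_edges:
        for e in graph.edges():
            v = float(table.entries.get(e.id, 0.0))
            if v > threshold:
                out.add_edge(e.source, e.target, e.interaction, **e.attributes)
        for node in graph.nodes():
            if out.has_node(node.id):
                out.add_node(node.id, **node.attributes)
            elif keep_orphans or float(table.entries.get(node.id, 0.0)) > threshold:
                out.add_node(node.id, **node.attributes)
    else:
        keep = {n.id for n in graph.nodes()
                if float(table.entries.get(n.id, 0.0)) > threshold}
        for nid in keep:
            out.add_node(nid, **graph.node(nid).attributes)
        for e in graph.edges():
            if e.source in keep and e.target in keep:
                out.add_edge(e.source, e.target, e.interaction, **e.attributes)
    return out


UNASSIGNED = "unassigned"


def split_by_attribute(graph: Graph, table: AttributeTable) -> list[tuple[str, Graph]]:
    """Partition into induced subgraphs, one per distinct attribute value.

    Mirrors splitting a pooled MS molecular network into per-condition
    networks by a filename attribute.  An edge belongs to a subgraph iff
    both endpoints share that value; cross-group edges appear in no
    subgraph.  Nodes missing from the table form a final ``"unassigned"``
    group (present only when non-empty).  Groups are ordered by sorted
    value, so the group node sets partition the input node set.
    """
    groups: dict[str, list[str]] = {}
    for node in graph.nodes():
        value = table.entries.get(node.id)
        key = UNASSIGNED if value is None else str(value)
        groups.setdefault(key, []).append(node.id)
    ordered = sorted(k for k in groups if k != UNASSIGNED)
    if UNASSIGNED in groups:
        ordered.append(UNASSIGNED)
    return [(value, graph.subgraph(groups[value])) for value in ordered]


# ------------------------------------------------------------------
# motion networks


@dataclass
class MutationEvent:
    """Atomic change to a graph or scene: insert/delete/update of a node,
    edge, or style entry.  ``payload`` carries the element record."""

    seq: int
    kind: str       # "insert" | "delete" | "update"
    target: str     # "node" | "edge" | "style"
    payload: dict

    def to_json(self) -> dict:
        return {"seq": self.seq, "kind": self.kind, "target": self.target,
                "payload": self.payload}

    @classmethod
    def from_json(cls, data: dict) -> "MutationEvent":
        return cls(int(data["seq"]), str(data["kind"]), str(data["target"]),
                   dict(data["payload"]))


@dataclass
class MotionNetwork:
    """Ordered frames over a union graph, stored as per-frame event lists."""

    union_graph: Graph
    frame_labels: list[str]
    events: list[list[MutationEvent]] = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return len(self.frame_labels)

    def replay(self, upto: int | None = None) -> Graph:
        """Rebuild the frame at index ``upto`` (default: last) from empty."""
        last = self.n_frames - 1 if upto is None else upto
        g = Graph(directed=self.union_graph.directed)
        for t in range(last + 1):
            g = apply_graph_events(g, self.events[t])
        return g

    def frames(self) -> list[Graph]:
        return [self.replay(t) for t in range(self.n_frames)]


def _node_record(graph: Graph, nid: str) -> dict:
    return {"id": nid, "attributes": dict(graph.node(nid).attributes)}


def _edge_record(graph: Graph, key: tuple[str, str, str]) -> dict:
    e = graph.edge(*key)
    return {"source": e.source, "target": e.target, "interaction": e.interaction,
            "attributes": dict(e.attributes)}


def diff_graphs(old: Graph, new: Graph, seq_start: int = 0) -> list[MutationEvent]:
    """Minimal event list turning ``old`` into ``new``.

    Order: edge deletions, node deletions, node insertions, edge
    insertions, then attribute updates — each block sorted by element id.
    Deleting a node implies its incident edges were deleted first.
    """
    events: list[MutationEvent] = []
    seq = seq_start
    old_nodes, new_nodes = set(old.node_ids()), set(new.node_ids())
    old_edges, new_edges = set(old.edge_keys()), set(new.edge_keys())

    def emit(kind: str, target: str, payload: dict) -> None:
        nonlocal seq
        events.append(MutationEvent(seq, kind, target, payload))
        seq += 1

    for key in sorted(old_edges - new_edges):
        emit("delete", "edge", _edge_record(old, key))
    for nid in sorted(old_nodes - new_nodes):
        emit("delete", "node", {"id": nid})
    for nid in sorted(new_nodes - old_nodes):
        emit("insert", "node", _node_record(new, nid))
    for key in sorted(new_edges - old_edges):
        emit("insert", "edge", _edge_record(new, key))
    for nid in sorted(old_nodes & new_nodes):
        if old.node(nid).attributes != new.node(nid).attributes:
            emit("update", "node", _node_record(new, nid))
    for key in sorted(old_edges & new_edges):
        if old.edge(*key).attributes != new.edge(*key).attributes:
            emit("update", "edge", _edge_record(new, key))
    return events


def apply_graph_events(graph: Graph, events: Iterable[MutationEvent]) -> Graph:
    """Apply structural events to a copy of ``graph`` and return it."""
    g = graph.copy()
    for ev in events:
        p = ev.payload
        if ev.target == "node":
            if ev.kind == "delete":
                g.remove_node(p["id"])
            elif ev.kind == "insert":
                if g.has_node(p["id"]):
                    raise ConfigError(f"insert of existing node {p['id']!r}")
                g.add_node(p["id"], **p.get("attributes", {}))
            else:
                g.node(p["id"]).attributes.clear()
                g.node(p["id"]).attributes.update(p.get("attributes", {}))
        elif ev.target == "edge":
            key = (p["source"], p["target"], p["interaction"])
            if ev.kind == "delete":
                g.remove_edge(*key)
            elif ev.kind == "insert":
                if g.has_edge(*key):
                    raise ConfigError(f"insert of existing edge {key}")
                g.add_edge(*key, **p.get("attributes", {}))
            else:
                e = g.edge(*key)
                e.attributes.clear()
                e.attributes.update(p.get("attributes", {}))
        else:
            raise ConfigError(f"graph replay cannot apply target {ev.target!r}")
    return g


def build_motion_network(frames: Sequence[Graph], labels: Sequence[str]) -> MotionNetwork:
    """Assemble a motion network from ordered frames.

    Events are set differences between consecutive frames (frame 0 diffs
    against the empty graph); the union graph collects every element that
    appears in any frame, with last-seen attributes.
    """
    if not frames:
        raise ConfigError("a motion network needs at least one frame")
    if len(labels) != len(frames):
        raise ConfigError(f"{len(frames)} frames but {len(labels)} labels")
    if len(set(labels)) != len(labels):
        raise ConfigError("frame labels must be unique")

    union = Graph(directed=frames[0].directed)
    for frame in frames:
        for node in frame.nodes():
            union.add_node(node.id, **node.attributes)
        for e in frame.edges():
            union.add_edge(e.source, e.target, e.interaction, **e.attributes)

    events: list[list[MutationEvent]] = []
    prev = Graph(directed=frames[0].directed)
    seq = 0
    for frame in frames:
        evs = diff_graphs(prev, frame, seq_start=seq)
        seq += len(evs)
        events.append(evs)
        prev = frame
    return MotionNetwork(union_graph=union, frame_labels=list(labels), events=events)


# ------------------------------------------------------------------
# animation


def animate(
    motion: MotionNetwork,
    layout: LayoutState | dict[str, tuple[float, float, float]],
    timeseries: TimeSeriesTable | None = None,
    style: VisualStyle | None = None,
    channel: str = "size",
) -> list[Scene]:
    """Render one :class:`Scene` per frame on the fixed union layout.

    Elements absent from a frame are hidden (left out of that frame's
    scene), not moved.  When a time-course table is given, its per-frame
    values drive the requested channel (``"size"``, ``"thickness"`` or
    ``"color"``) via the style's ranges; the table's ids must exist in the
    frame they style.
    """
    positions = layout.positions if isinstance(layout, LayoutState) else dict(layout)
    style = style or VisualStyle()
    if channel not in ("size", "thickness", "color"):
        raise ConfigError(f"unknown channel {channel!r}")
    if timeseries is not None and timeseries.n_frames != motion.n_frames:
        raise ConfigError(
            f"time course has {timeseries.n_frames} frames, motion has {motion.n_frames}")
    missing = [n for n in motion.union_graph.node_ids() if n not in positions]
    if missing:
        raise GraphLookupError(missing[0])

    scenes: list[Scene] = []
    for t in range(motion.n_frames):
        frame = motion.replay(t)
        scene = Scene(
            graph=frame,
            positions={n: positions[n] for n in frame.node_ids()},
        )
        if timeseries is not None:
            frame_values = timeseries.frame(t)
            node_ids = set(frame.node_ids())
            frame_edge_ids = {e.id for e in frame.edges()}
            union_ids = set(motion.union_graph.node_ids()) | {
                e.id for e in motion.union_graph.edges()}
            for eid in frame_values:
                # ids hidden in this frame are fine; ids in no frame are not
                if eid not in union_ids:
                    raise GraphLookupError(
                        f"frame {motion.frame_labels[t]!r}: no such element {eid!r}")
            if channel == "size":
                scene.node_size.update(map_values_to_size(
                    {k: v for k, v in frame_values.items() if k in node_ids}, style))
            elif channel == "thickness":
                scene.edge_thickness.update(map_values_to_thickness(
                    {k: v for k, v in frame_values.items() if k in frame_edge_ids}, style))
            else:
                scene.node_color.update(map_values_to_color(
                    {k: v for k, v in frame_values.items() if k in node_ids},
                    style.color_scheme))
        scene.validate()
        scenes.append(scene)
    return scenes
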