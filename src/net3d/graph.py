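"""Attributed network model, visual styles, scenes, and node search.

The :class:`Graph` is the universal currency of the package: a collection of
uniquely-identified nodes and interaction-typed edges, optionally directed.
Edges are keyed by ``(source, target, interaction)``; in undirected mode the
key is canonicalized so that ``(a, b, i)`` and ``(b, a, i)`` denote the same
edge.  Adding an edge auto-creates missing endpoint nodes (SIF semantics), so
a graph can never hold a dangling edge.  Duplicate edges collapse to one,
keeping the last-seen attributes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import networkx as nx

from .errors import GraphLookupError, ParameterError

AttrValue = str | float | int
EdgeKey = tuple[str, str, str]

_EDGE_ID_RE = re.compile(r"^(?P<s>.+?) \((?P<i>[^()]*)\) (?P<t>.+)$")


@dataclass
class Node:
    """A network node: a unique non-empty text id plus free-form attributes."""

    id: str
    attributes: dict[str, AttrValue] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.id:
            raise ParameterError("node id must be non-empty")


@dataclass
class Edge:
    """An interaction-typed edge between two node ids."""

    source: str
    target: str
    interaction: str
    attributes: dict[str, AttrValue] = field(default_factory=dict)

    @property
    def id(self) -> str:
        """Cytoscape-style edge identifier, e.g. ``"A (pp) B"``."""
        return f"{self.source} ({self.interaction}) {self.target}"


def edge_id(source: str, target: str, interaction: str) -> str:
    return f"{source} ({interaction}) {target}"


def parse_edge_id(text: str) -> EdgeKey:
    """Invert :func:`edge_id`; raises :class:`GraphLookupError` on bad syntax."""
    m = _EDGE_ID_RE.match(text)
    if m is None:
        raise GraphLookupError(text)
    return m.group("s"), m.group("t"), m.group("i")


class Graph:
    """Attributed graph with unique node ids and interaction-typed edges."""

    def __init__(self, directed: bool = False):
        self.directed = directed
        self._nodes: dict[str, Node] = {}
        self._edges: dict[EdgeKey, Edge] = {}
        self._adj: dict[str, set[str]] = {}

    # -- construction -------------------------------------------------

    def _canon(self, source: str, target: str, interaction: str) -> EdgeKey:
        if not self.directed and target < source:
            source, target = target, source
        return source, target, interaction

    def add_node(self, node_id: str, **attributes: AttrValue) -> Node:
        node = self._nodes.get(node_id)
        if node is None:
            node = Node(node_id)
            self._nodes[node_id] = node
            self._adj[node_id] = set()
        node.attributes.update(attributes)
        return node

    def add_edge(
        self, source: str, target: str, interaction: str = "pp", **attributes: AttrValue
    ) -> Edge:
        """Add (or update) an edge; missing endpoint nodes are auto-created."""
        self.add_node(source)
        self.add_node(target)
        key = self._canon(source, target, interaction)
        edge = self._edges.get(key)
        if edge is None:
            edge = Edge(source, target, interaction)
            self._edges[key] = edge
            self._adj[source].add(target)
            self._adj[target].add(source)
        edge.attributes.update(attributes)
        return edge

    def remove_edge(self, source: str, target: str, interaction: str) -> None:
        key = self._canon(source, target, interaction)
        if key not in self._edges:
            raise GraphLookupError(edge_id(source, target, interaction))
        del self._edges[key]
        if not any(
            (a == source and b == target) or (not self.directed and a == target and b == source)
            for a, b, _ in self._edges
        ):
            self._adj[source].discard(target)
            self._adj[target].discard(source)

    def remove_node(self, node_id: str) -> None:
        if node_id not in self._nodes:
            raise GraphLookupError(node_id)
        for key in [k for k in self._edges if node_id in (k[0], k[1])]:
            del self._edges[key]
        for nbrs in self._adj.values():
            nbrs.discard(node_id)
        del self._adj[node_id]
        del self._nodes[node_id]

    # -- inspection ---------------------------------------------------

    def __len__(self) -> int:
        return len(self._nodes)

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def nodes(self) -> Iterator[Node]:
        return iter(self._nodes.values())

    def node_ids(self) -> list[str]:
        return list(self._nodes)

    def edges(self) -> Iterator[Edge]:
        return iter(self._edges.values())

    def edge_keys(self) -> list[EdgeKey]:
        return list(self._edges)

    def has_node(self, node_id: str) -> bool:
        return node_id in self._nodes

    def has_edge(self, source: str, target: str, interaction: str = "pp") -> bool:
        return self._canon(source, target, interaction) in self._edges

    def node(self, node_id: str) -> Node:
        try:
            return self._nodes[node_id]
        except KeyError:
            raise GraphLookupError(node_id) from None

    def edge(self, source: str, target: str, interaction: str = "pp") -> Edge:
        key = self._canon(source, target, interaction)
        try:
            return self._edges[key]
        except KeyError:
            raise GraphLookupError(edge_id(source, target, interaction)) from None

    def neighbors(self, node_id: str) -> set[str]:
        """Neighbor ids over the simple-graph view (self-loops excluded)."""
        if node_id not in self._adj:
            raise GraphLookupError(node_id)
        return {n for n in self._adj[node_id] if n != node_id}

    def degree(self, node_id: str) -> int:
        return len(self.neighbors(node_id))

    def isolated_nodes(self) -> list[str]:
        return [n for n, nbrs in self._adj.items() if not nbrs]

    def copy(self) -> "Graph":
        g = Graph(directed=self.directed)
        for node in self.nodes():
            g.add_node(node.id, **node.attributes)
        for e in self.edges():
            g.add_edge(e.source, e.target, e.interaction, **e.attributes)
        return g

    def subgraph(self, node_ids: Iterable[str]) -> "Graph":
        """Induced subgraph on ``node_ids`` (unknown ids ignored)."""
        keep = {n for n in node_ids if n in self._nodes}
        g = Graph(directed=self.directed)
        for nid in keep:
            g.add_node(nid, **self._nodes[nid].attributes)
        for e in self.edges():
            if e.source in keep and e.target in keep:
                g.add_edge(e.source, e.target, e.interaction, **e.attributes)
        return g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Graph):
            return NotImplemented
        return (
            self.directed == other.directed
            and {n.id: n.attributes for n in self.nodes()}
            == {n.id: n.attributes for n in other.nodes()}
            and {k: self._edges[k].attributes for k in self._edges}
            == {k: other._edges[k].attributes for k in other._edges}
        )

    def same_topology(self, other: "Graph") -> bool:
        return set(self._nodes) == set(other._nodes) and set(self._edges) == set(other._edges)

    def to_networkx(self) -> nx.Graph | nx.DiGraph:
        g: nx.Graph | nx.DiGraph = nx.DiGraph() if self.directed else nx.Graph()
        for node in self.nodes():
            g.add_node(node.id, **node.attributes)
        for e in self.edges():
            g.add_edge(e.source, e.target, interaction=e.interaction, **e.attributes)
        return g


# -- search / attribute lookup ----------------------------------------


def find_nodes(graph: Graph, query: str) -> list[str]:
    """Node ids containing ``query`` as a case-insensitive substring, sorted.

    Mirrors an interactive search box: ids are case-sensitive for identity
    but matching is case-insensitive; no match yields an empty list.
    """
    if not query:
        raise ParameterError("search query must be non-empty")
    q = query.lower()
    return sorted(n for n in graph.node_ids() if q in n.lower())


def get_attributes(graph: Graph, element_id: str) -> Mapping[str, AttrValue]:
    """Full attribute mapping of a node id or ``"A (pp) B"`` edge id."""
    if graph.has_node(element_id):
        return dict(graph.node(element_id).attributes)
    try:
        s, t, i = parse_edge_id(element_id)
        return dict(graph.edge(s, t, i).attributes)
    except GraphLookupError:
        raise GraphLookupError(element_id) from None


# -- visual style and scene -------------------------------------------

Color = tuple[float, float, float]

#: Named value→color ramps (three anchors at min / mid / max of the value
#: range).  "heatmap" is the expression heat-map convention: low values cold
#: blue, high values hot yellow, through black.
COLOR_SCHEMES: dict[str, tuple[Color, Color, Color]] = {
    "heatmap": ((0.0, 0.0, 1.0), (0.0, 0.0, 0.0), (1.0, 1.0, 0.0)),
    "grayscale": ((0.0, 0.0, 0.0), (0.5, 0.5, 0.5), (1.0, 1.0, 1.0)),
    "red-green": ((1.0, 0.0, 0.0), (0.0, 0.0, 0.0), (0.0, 1.0, 0.0)),
}


def color_to_hex(color: Color) -> str:
    r, g, b = (max(0.0, min(1.0, c)) for c in color)
    return f"#{round(r * 255):02x}{round(g * 255):02x}{round(b * 255):02x}"


def hex_to_color(text: str) -> Color:
    text = text.lstrip("#")
    return tuple(int(text[i : i + 2], 16) / 255 for i in (0, 2, 4))  # type: ignore[return-value]


@dataclass
class VisualStyle:
    """Ranges and color ramp used to map numeric values to visual channels."""

    size_range: tuple[float, float] = (10.0, 40.0)
    thickness_range: tuple[float, float] = (1.0, 8.0)
    color_scheme: str = "heatmap"
    default_color: Color = (0.6, 0.6, 0.6)

    def __post_init__(self) -> None:
        for name, (lo, hi) in (("size_range", self.size_range), ("thickness_range", self.thickness_range)):
            if not (0 < lo < hi):
                raise ParameterError(f"{name} must satisfy 0 < min < max, got {(lo, hi)}")


@dataclass
class Scene:
    """A renderable snapshot: graph + 3D positions + per-element styling."""

    graph: Graph
    positions: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    node_size: dict[str, float] = field(default_factory=dict)
    node_color: dict[str, Color] = field(default_factory=dict)
    edge_thickness: dict[str, float] = field(default_factory=dict)
    edge_color: dict[str, Color] = field(default_factory=dict)
    highlighted: set[str] = field(default_factory=set)

    def validate(self) -> None:
        """Check that every styled / positioned element exists in the graph."""
        node_ids = set(self.graph.node_ids())
        edge_ids = {e.id for e in self.graph.edges()}
        for mapping in (self.positions, self.node_size, self.node_color):
            for nid in mapping:
                if nid not in node_ids:
                    raise GraphLookupError(nid)
        for mapping in (self.edge_thickness, self.edge_color):
            for eid in mapping:
                if eid not in edge_ids:
                    raise GraphLookupError(eid)
        for nid in self.highlighted:
            if nid not in node_ids:
                raise GraphLookupError(nid)

    def highlight(self, node_ids: Iterable[str]) -> None:
        """Label the given nodes as highlighted; nothing else changes."""
        for nid in node_ids:
            if not self.graph.has_node(nid):
                raise GraphLookupError(nid)
            self.highlighted.add(nid)

    def copy(self) -> "Scene":
        return Scene(
            graph=self.graph.copy(),
            positions=dict(self.positions),
            node_size=dict(self.node_size),
            node_color=dict(self.node_color),
            edge_thickness=dict(self.edge_thickness),
            edge_color=dict(self.edge_color),
            highlighted=set(self.highlighted),
        )
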