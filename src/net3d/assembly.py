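"""De Bruijn assembly graphs: Velvet LastGraph content, network conversion,
and bubble detection.

A Velvet assembly graph consists of length/coverage-annotated nodes (each a
run of overlapping k-mers) and orientation-signed arcs: an arc ``(+a, -b)``
connects one strand-end of contig ``a`` to one of contig ``b``, and every arc
has a reverse-complement twin ``(+b, -a)`` describing the same physical
junction.  For network visualization and bubble screening we fold the
orientation away: both signed forms collapse to a single undirected edge
``a -- b`` whose ``multiplicity`` attribute accumulates the arc
multiplicities (read support).

Bubbles
-------
A *bubble* is a pair of nodes joined by two or more alternative unbranched
paths — the signature that sequencing errors or biological variants (SNPs,
small indels) leave in a de Bruijn graph.  Formally, a bubble here is an
unordered node pair ``(source, sink)`` admitting at least two distinct simple
paths of at most ``max_path_len`` edges whose internal nodes all have degree
exactly 2.  Two such paths are automatically internally node-disjoint: a
degree-2 interior node determines both of its path edges, so paths sharing
one interior node coincide entirely.  On a pure cycle (every node degree 2)
the qualifying endpoint pairs are symmetric and all describe the same cycle;
such pairs are grouped by the node set of their path family and the group is
reported once, with the lexicographically smallest qualifying pair as its
representative endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import FormatError, GraphLookupError, ParameterError
from .graph import Graph


@dataclass
class AssemblyNode:
    """One LastGraph NODE block: id, length in k-mers, coverage columns."""

    id: int
    length: int
    coverage: tuple[float, ...] = ()
    sequences: tuple[str, str] = ("", "")


@dataclass
class AssemblyArc:
    """One ARC record; ``start``/``end`` are orientation-signed node ids."""

    start: int
    end: int
    multiplicity: int = 1


@dataclass
class AssemblyGraph:
    """Parsed Velvet LastGraph content."""

    nodes: list[AssemblyNode] = field(default_factory=list)
    arcs: list[AssemblyArc] = field(default_factory=list)
    hash_length: int = 21
    sequence_count: int = 0
    extra_header: tuple[str, ...] = ()

    def node_ids(self) -> set[int]:
        return {n.id for n in self.nodes}

    def validate(self) -> None:
        ids = self.node_ids()
        for arc in self.arcs:
            for endpoint in (arc.start, arc.end):
                if abs(endpoint) not in ids:
                    raise FormatError(f"ARC references undeclared node {endpoint}")
            if arc.multiplicity < 1:
                raise FormatError(f"ARC {arc.start} {arc.end} has multiplicity < 1")


def assembly_to_graph(asm: AssemblyGraph, keep_orientation: bool = False) -> Graph:
    """Convert an assembly graph to a network.

    Default (folded) mode: one network node per assembly node; an arc
    ``(±a, ±b)`` becomes the undirected edge ``a -- b`` with interaction
    ``"arc"``; twin/duplicate arcs merge with multiplicities summed into the
    edge's ``multiplicity`` attribute; self-arcs become self-loop edges.
    Node attributes carry ``length`` and ``coverage``.

    With ``keep_orientation=True`` each assembly node becomes two directed
    nodes ``<id>+`` / ``<id>-`` and arcs keep their strand semantics.
    """
    asm.validate()
    if keep_orientation:
        g = Graph(directed=True)
        for node in asm.nodes:
            for strand in ("+", "-"):
                g.add_node(f"{node.id}{strand}", length=node.length,
                           coverage=sum(node.coverage) if node.coverage else 0.0)
        for arc in asm.arcs:
            s = f"{abs(arc.start)}{'+' if arc.start > 0 else '-'}"
            t = f"{abs(arc.end)}{'+' if arc.end > 0 else '-'}"
            e = g.add_edge(s, t, "arc")
            e.attributes["multiplicity"] = e.attributes.get("multiplicity", 0) + arc.multiplicity
        return g

    g = Graph(directed=False)
    for node in asm.nodes:
        g.add_node(str(node.id), length=node.length,
                   coverage=sum(node.coverage) if node.coverage else 0.0)
    for arc in asm.arcs:
        s, t = str(abs(arc.start)), str(abs(arc.end))
        e = g.add_edge(s, t, "arc")
        e.attributes["multiplicity"] = e.attributes.get("multiplicity", 0) + arc.multiplicity
    return g


@dataclass
class Bubble:
    """A detected bubble: endpoints plus its internally disjoint path family."""

    source: str
    sink: str
    paths: list[list[str]]
    max_path_len: int

    @property
    def n_paths(self) -> int:
        return len(self.paths)


def _chains(graph: Graph) -> tuple[list[list[str]], set[str]]:
    """Decompose the simple-graph view into unbranched chains.

    An *anchor* is a node whose degree differs from 2.  A chain runs from an
    anchor through consecutive degree-2 nodes to the next anchor (possibly
    the same one, closing a cycle).  Returns the chain list (each a node-id
    path, recorded once) and the set of degree-2 nodes not covered by any
    chain — these form pure-cycle components.
    """
    anchors = {n for n in graph.node_ids() if graph.degree(n) != 2}
    chains: list[list[str]] = []
    used_dir: set[tuple[str, str]] = set()  # (anchor, first-step) already walked
    covered: set[str] = set()
    for a in sorted(anchors):
        for first in sorted(graph.neighbors(a)):
            if (a, first) in used_dir:
                continue
            path = [a, first]
            prev, cur = a, first
            while cur not in anchors:
                covered.add(cur)
                nxt = next(iter(graph.neighbors(cur) - {prev}))
                path.append(nxt)
                prev, cur = cur, nxt
            used_dir.add((a, first))
            used_dir.add((path[-1], path[-2]))
            chains.append(path)
    leftovers = {n for n in graph.node_ids()
                 if graph.degree(n) == 2 and n not in anchors and n not in covered}
    return chains, leftovers


def _cycle_from(graph: Graph, start: str, members: set[str]) -> list[str]:
    """Trace the pure cycle through ``start`` (all members degree 2)."""
    cycle = [start]
    prev, cur = None, start
    while True:
        nbrs = sorted(graph.neighbors(cur))
        nxt = nbrs[0] if nbrs[0] != prev else nbrs[1]
        if nxt == start:
            return cycle
        cycle.append(nxt)
        prev, cur = cur, nxt


def detect_bubbles(graph: Graph, max_path_len: int = 10) -> list[Bubble]:
    """Find all bubbles with per-path length bound ``max_path_len`` (edges).

    Algorithm: decompose the graph into unbranched chains between anchor
    nodes (degree != 2), then (a) an anchor pair joined by >= 2 chains of
    length <= ``max_path_len`` is a bubble; (b) a chain returning to its own
    anchor (an attached cycle of c edges) is a bubble iff it can be split
    into two halves of <= ``max_path_len`` edges each, i.e. ceil(c/2) <=
    ``max_path_len``; (c) a pure-cycle component likewise.  Nested bubbles
    count separately per distinct endpoint pair; symmetric endpoint choices
    on one cycle are collapsed to a single report.
    """
    if max_path_len < 2:
        raise ParameterError(f"max_path_len must be >= 2, got {max_path_len}")
    L = max_path_len
    chains, leftover = _chains(graph)

    bubbles: list[Bubble] = []

    # (a) anchor pairs with parallel chains
    by_pair: dict[tuple[str, str], list[list[str]]] = {}
    self_chains: list[list[str]] = []
    for path in chains:
        a, b = path[0], path[-1]
        if a == b:
            self_chains.append(path)
            continue
        key = (a, b) if a < b else (b, a)
        by_pair.setdefault(key, []).append(path if a < b else path[::-1])
    for (s, t), paths in sorted(by_pair.items()):
        short = [p for p in paths if len(p) - 1 <= L]
        if len(short) >= 2:
            bubbles.append(Bubble(s, t, sorted(short, key=lambda p: (len(p), p)), L))

    # (b) cycles attached to a single anchor; (c) pure-cycle components
    cycles: list[list[str]] = []
    for path in self_chains:
        cycles.append(path[:-1])  # drop repeated anchor at the end
    seen: set[str] = set()
    for n in sorted(leftover):
        if n in seen:
            continue
        cyc = _cycle_from(graph, n, leftover)
        seen.update(cyc)
        cycles.append(cyc)
    for cyc in cycles:
        c = len(cyc)
        if (c + 1) // 2 > L:
            continue
        # qualifying endpoint pairs are symmetric around the cycle: report
        # once, with the lexicographically smallest qualifying pair.  On an
        # attached cycle only pairs containing the anchor qualify (the other
        # way around any interior pair passes through the anchor, whose
        # degree exceeds 2).
        anchorage = [cyc[0]] if graph.degree(cyc[0]) != 2 else cyc
        best: tuple[str, str] | None = None
        best_paths: list[list[str]] = []
        for s in anchorage:
            i = cyc.index(s)
            for j in range(c):
                if j == i:
                    continue
                d = (j - i) % c
                if max(d, c - d) > L:
                    continue
                pair = tuple(sorted((s, cyc[j])))
                if best is None or pair < best:
                    fwd = [cyc[(i + step) % c] for step in range(d + 1)]
                    bwd = [cyc[(i - step) % c] for step in range(c - d + 1)]
                    best = pair  # type: ignore[assignment]
                    best_paths = [fwd, bwd] if fwd[0] == best[0] else [fwd[::-1], bwd[::-1]]
        if best is not None:
            src, snk = best
            paths = [p if p[0] == src else p[::-1] for p in best_paths]
            bubbles.append(Bubble(src, snk, sorted(paths, key=lambda p: (len(p), p)), L))

    bubbles.sort(key=lambda b: (b.source, b.sink))
    return bubbles


def connection_report(graph: Graph, node_id: str) -> dict[str, list[dict[str, object]]]:
    """Tabulate a node's connections, grouped by interaction type.

    Supports the contig-scaffolding use case: for a contig node the report
    lists every neighboring contig with the summed read-pair multiplicity of
    their merged edges (and any end labels the edges carry).
    """
    if not graph.has_node(node_id):
        raise GraphLookupError(node_id)
    report: dict[str, list[dict[str, object]]] = {}
    for e in graph.edges():
        if node_id not in (e.source, e.target):
            continue
        other = e.target if e.source == node_id else e.source
        entry: dict[str, object] = {"neighbor": other}
        entry.update(e.attributes)
        report.setdefault(e.interaction, []).append(entry)
    for rows in report.values():
        rows.sort(key=lambda r: str(r["neighbor"]))
    return report
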