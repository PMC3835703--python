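"""Readers and writers for the formats the toolkit touches.

Text formats handled here:

* **SIF** (Simple Interaction Format): ``source interaction target [target2
  ...]`` per line; a single-token line declares an isolated node.  Delimiter
  is any whitespace run, except that a line containing a tab is split on
  tabs (Cytoscape's dual-dialect rule, which allows ids with spaces).
* **Cytoscape node/edge attribute files** (.NA/.EA): attribute name on the
  first line, then ``id = value`` lines.
* **Time-course tables**: tab-separated, header ``id<TAB>frame1<TAB>...``,
  one row of numeric values per element.
* **Velvet LastGraph**: header ``node_count sequence_count hash_length ...``,
  ``NODE`` blocks with two sequence lines, ``ARC`` lines with
  orientation-signed node ids.  Short-read tracking records (NR/SEQ) are
  preserved verbatim but not interpreted.
* **GraphML** (via networkx) with layout coordinates stored as node
  attributes ``x``, ``y``, ``z``.
* **Scene JSON**: this package's documented scene snapshot format (see
  ``docs/protocol.md``).
"""

from __future__ import annotations

import io as _io
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, TextIO

import networkx as nx
import pandas as pd

from .assembly import AssemblyArc, AssemblyGraph, AssemblyNode
from .errors import FormatError, GraphLookupError
from .graph import Color, Graph, Scene

SCENE_SCHEMA_VERSION = 1


def _as_stream(source: str | TextIO) -> TextIO:
    return _io.StringIO(source) if isinstance(source, str) else source


# ---------------------------------------------------------------- SIF


def _split_sif(line: str) -> list[str]:
    return [t for t in (line.split("\t") if "\t" in line else line.split()) if t != ""]


def read_sif(source: str | TextIO, directed: bool = False) -> Graph:
    """Parse a SIF stream (or literal string) into a :class:`Graph`."""
    g = Graph(directed=directed)
    for lineno, raw in enumerate(_as_stream(source), start=1):
        tokens = _split_sif(raw.rstrip("\n"))
        if not tokens:
            continue
        if len(tokens) == 1:
            g.add_node(tokens[0])
        elif len(tokens) == 2:
            raise FormatError("SIF line has a source and interaction but no target", line=lineno)
        else:
            src, interaction = tokens[0], tokens[1]
            for target in tokens[2:]:
                g.add_edge(src, target, interaction)
    return g


def write_sif(graph: Graph) -> str:
    """Serialize topology: one edge per line, isolated nodes as single tokens."""
    lines = [f"{e.source}\t{e.interaction}\t{e.target}" for e in graph.edges()]
    lines += graph.isolated_nodes()
    return "\n".join(lines) + ("\n" if lines else "")


# ------------------------------------------------- attribute files


@dataclass
class AttributeTable:
    """A named per-element attribute column (Cytoscape .NA/.EA content)."""

    name: str
    entries: dict[str, str | float] = field(default_factory=dict)
    value_kind: str = "text"  # "text" | "number"

    def __post_init__(self) -> None:
        if self.value_kind not in ("text", "number"):
            raise FormatError(f"unknown value_kind {self.value_kind!r}")


def read_node_attributes(source: str | TextIO) -> AttributeTable:
    """Read a Cytoscape attribute file.

    The first non-blank line names the attribute (a trailing
    ``(class=...)`` annotation is ignored); subsequent lines are
    ``id = value``.  Duplicate ids keep the last value.  The table is
    numeric iff every value parses as a number; otherwise all values stay
    text.
    """
    stream = _as_stream(source)
    name: str | None = None
    raw_entries: dict[str, str] = {}
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line:
            continue
        if name is None:
            name = line.split("(class=")[0].strip()
            continue
        if " = " not in line:
            raise FormatError("attribute line lacks ' = ' separator", line=lineno)
        key, _, value = line.partition(" = ")
        key, value = key.strip(), value.strip()
        if not key:
            raise FormatError("attribute line has an empty id", line=lineno)
        raw_entries[key] = value
    if name is None:
        raise FormatError("attribute file is empty (no attribute name line)")

    def _num(v: str) -> float | None:
        try:
            x = float(v)
        except ValueError:
            return None
        return x if math.isfinite(x) else None

    numeric = {k: _num(v) for k, v in raw_entries.items()}
    if raw_entries and all(v is not None for v in numeric.values()):
        return AttributeTable(name, {k: float(v) for k, v in numeric.items()}, "number")  # type: ignore[arg-type]
    return AttributeTable(name, dict(raw_entries), "text")


def write_node_attributes(table: AttributeTable) -> str:
    lines = [table.name]
    lines += [f"{k} = {v:g}" if table.value_kind == "number" else f"{k} = {v}"
              for k, v in table.entries.items()]
    return "\n".join(lines) + "\n"


# ------------------------------------------------- time-course tables


@dataclass
class TimeSeriesTable:
    """Per-element numeric trajectories over an ordered set of frames."""

    frame_labels: list[str]
    values: dict[str, list[float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.frame_labels)) != len(self.frame_labels):
            raise FormatError("frame labels must be unique")
        for key, row in self.values.items():
            if len(row) != len(self.frame_labels):
                raise FormatError(
                    f"row has {len(row)} values for {len(self.frame_labels)} frames",
                    locator=f"row {key!r}",
                )

    @property
    def n_frames(self) -> int:
        return len(self.frame_labels)

    def frame(self, index: int) -> dict[str, float]:
        """Values of all elements at one frame index."""
        return {k: row[index] for k, row in self.values.items()}


def read_timeseries(source: str | TextIO) -> TimeSeriesTable:
    """Read a tab-separated time-course table (header: id, then frames)."""
    try:
        df = pd.read_csv(_as_stream(source), sep="\t", dtype={0: str}, index_col=0)
    except pd.errors.ParserError as exc:
        raise FormatError(f"malformed time-course table: {exc}") from None
    except pd.errors.EmptyDataError:
        raise FormatError("time-course table is empty (no header)") from None
    frame_labels = [str(c) for c in df.columns]
    values: dict[str, list[float]] = {}
    for rid, row in df.iterrows():
        vals = row.to_numpy(dtype=object)
        numeric: list[float] = []
        for v in vals:
            try:
                x = float(v)
            except (TypeError, ValueError):
                raise FormatError("non-numeric cell", locator=f"row {rid!r}") from None
            if not math.isfinite(x):
                raise FormatError("missing or non-finite cell", locator=f"row {rid!r}")
            numeric.append(x)
        values[str(rid)] = numeric
    return TimeSeriesTable(frame_labels, values)


def write_timeseries(table: TimeSeriesTable) -> str:
    lines = ["id\t" + "\t".join(table.frame_labels)]
    for rid, row in table.values.items():
        lines.append(rid + "\t" + "\t".join(f"{v:g}" for v in row))
    return "\n".join(lines) + "\n"


# ------------------------------------------------- Velvet LastGraph


def read_lastgraph(source: str | TextIO) -> AssemblyGraph:
    """Parse a Velvet LastGraph stream into an :class:`AssemblyGraph`."""
    lines = _as_stream(source).read().splitlines()
    idx = 0
    while idx < len(lines) and not lines[idx].strip():
        idx += 1
    if idx == len(lines):
        raise FormatError("LastGraph is empty", line=1)
    header = lines[idx].split()
    if len(header) < 3:
        raise FormatError("LastGraph header needs at least node_count, sequence_count, hash_length",
                          line=idx + 1)
    try:
        node_count, seq_count, hash_len = int(header[0]), int(header[1]), int(header[2])
    except ValueError:
        raise FormatError("non-integer LastGraph header field", line=idx + 1) from None
    asm = AssemblyGraph(hash_length=hash_len, sequence_count=seq_count,
                        extra_header=tuple(header[3:]))
    idx += 1
    while idx < len(lines):
        line = lines[idx]
        fields = line.split()
        if not fields:
            idx += 1
            continue
        tag = fields[0]
        if tag == "NODE":
            if len(fields) < 3:
                raise FormatError("NODE line needs at least an id and a length", line=idx + 1)
            try:
                nid, length = int(fields[1]), int(fields[2])
                coverage = tuple(float(x) for x in fields[3:])
            except ValueError:
                raise FormatError("non-numeric NODE field", line=idx + 1) from None
            seqs = []
            for off in (1, 2):
                seqs.append(lines[idx + off] if idx + off < len(lines) else "")
            asm.nodes.append(AssemblyNode(nid, length, coverage, (seqs[0], seqs[1])))
            idx += 3
        elif tag == "ARC":
            if len(fields) < 3:
                raise FormatError("ARC line needs start and end node ids", line=idx + 1)
            try:
                start, end = int(fields[1]), int(fields[2])
                mult = int(fields[3]) if len(fields) > 3 else 1
            except ValueError:
                raise FormatError("non-numeric ARC field", line=idx + 1) from None
            declared = asm.node_ids()
            for endpoint in (start, end):
                if abs(endpoint) not in declared:
                    raise FormatError(f"ARC references undeclared node {endpoint}", line=idx + 1)
            asm.arcs.append(AssemblyArc(start, end, mult))
            idx += 1
        elif tag in ("NR", "SEQ"):
            # short-read tracking records: skipped (topology-only conversion)
            idx += 1
        else:
            idx += 1
    if len(asm.nodes) != node_count:
        raise FormatError(
            f"header declares {node_count} nodes but {len(asm.nodes)} NODE blocks found")
    return asm


def write_lastgraph(asm: AssemblyGraph) -> str:
    header = f"{len(asm.nodes)}\t{asm.sequence_count}\t{asm.hash_length}"
    if asm.extra_header:
        header += "\t" + "\t".join(asm.extra_header)
    lines = [header]
    for node in asm.nodes:
        cov = "\t".join(f"{c:g}" for c in node.coverage)
        lines.append(f"NODE\t{node.id}\t{node.length}" + (f"\t{cov}" if cov else ""))
        lines.append(node.sequences[0])
        lines.append(node.sequences[1])
    for arc in asm.arcs:
        lines.append(f"ARC\t{arc.start}\t{arc.end}\t{arc.multiplicity}")
    return "\n".join(lines) + "\n"


# ------------------------------------------------- GraphML


def export_graphml(graph: Graph, positions: dict[str, tuple[float, float, float]]) -> str:
    """Serialize graph + layout to GraphML; coordinates become x/y/z attrs."""
    missing = [n for n in graph.node_ids() if n not in positions]
    if missing:
        raise GraphLookupError(missing[0])
    g = graph.to_networkx()
    for nid, (x, y, z) in positions.items():
        if g.has_node(nid):
            g.nodes[nid]["x"], g.nodes[nid]["y"], g.nodes[nid]["z"] = float(x), float(y), float(z)
    return "\n".join(nx.generate_graphml(g))


def import_graphml(source: str | TextIO) -> tuple[Graph, dict[str, tuple[float, float, float]]]:
    text = source if isinstance(source, str) else source.read()
    g = nx.parse_graphml(text)
    graph = Graph(directed=g.is_directed())
    positions: dict[str, tuple[float, float, float]] = {}
    for nid, data in g.nodes(data=True):
        attrs = {k: v for k, v in data.items() if k not in ("x", "y", "z")}
        graph.add_node(str(nid), **attrs)
        if all(k in data for k in ("x", "y", "z")):
            positions[str(nid)] = (float(data["x"]), float(data["y"]), float(data["z"]))
    for s, t, data in g.edges(data=True):
        interaction = str(data.get("interaction", "pp"))
        attrs = {k: v for k, v in data.items() if k != "interaction"}
        graph.add_edge(str(s), str(t), interaction, **attrs)
    return graph, positions


# ------------------------------------------------- scene JSON


def export_scene(scene: Scene) -> str:
    """Serialize a scene snapshot to the package's scene-JSON format."""
    scene.validate()
    missing = [n for n in scene.graph.node_ids() if n not in scene.positions]
    if missing:
        raise GraphLookupError(missing[0])
    nodes = []
    for node in sorted(scene.graph.nodes(), key=lambda n: n.id):
        x, y, z = scene.positions[node.id]
        rec = {
            "id": node.id,
            "x": x, "y": y, "z": z,
            "label": node.id in scene.highlighted,
            "attributes": node.attributes,
        }
        # style channels are optional; omitting unset ones keeps snapshots
        # lossless, which the sync join protocol relies on
        if node.id in scene.node_size:
            rec["size"] = scene.node_size[node.id]
        if node.id in scene.node_color:
            rec["color"] = list(scene.node_color[node.id])
        nodes.append(rec)
    edges = []
    for e in sorted(scene.graph.edges(), key=lambda e: e.id):
        rec = {
            "source": e.source,
            "target": e.target,
            "interaction": e.interaction,
            "attributes": e.attributes,
        }
        if e.id in scene.edge_thickness:
            rec["thickness"] = scene.edge_thickness[e.id]
        if e.id in scene.edge_color:
            rec["color"] = list(scene.edge_color[e.id])
        edges.append(rec)
    return json.dumps({
        "schema": SCENE_SCHEMA_VERSION,
        "directed": scene.graph.directed,
        "nodes": nodes,
        "edges": edges,
    }, indent=2, sort_keys=True)


def import_scene(source: str | TextIO) -> Scene:
    text = source if isinstance(source, str) else source.read()
    data = json.loads(text)
    graph = Graph(directed=bool(data.get("directed", False)))
    scene = Scene(graph=graph)
    for rec in data.get("nodes", []):
        graph.add_node(rec["id"], **rec.get("attributes", {}))
        scene.positions[rec["id"]] = (float(rec["x"]), float(rec["y"]), float(rec["z"]))
        if "size" in rec:
            scene.node_size[rec["id"]] = float(rec["size"])
        if "color" in rec:
            scene.node_color[rec["id"]] = tuple(float(c) for c in rec["color"])
        if rec.get("label"):
            scene.highlighted.add(rec["id"])
    for rec in data.get("edges", []):
        e = graph.add_edge(rec["source"], rec["target"], rec.get("interaction", "pp"),
                           **rec.get("attributes", {}))
        if "thickness" in rec:
            scene.edge_thickness[e.id] = float(rec["thickness"])
        if "color" in rec:
            scene.edge_color[e.id] = tuple(float(c) for c in rec["color"])
    return scene


def export_scene_sequence(scenes: Iterable[Scene]) -> str:
    """Serialize an animation: an ordered JSON array of scene snapshots."""
    return json.dumps([json.loads(export_scene(s)) for s in scenes], indent=2, sort_keys=True)
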