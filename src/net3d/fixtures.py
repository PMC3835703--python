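"""Seeded synthetic-data generators.

Every generator is a pure function of its parameters and seed, and emits
data that round-trips through :mod:`net3d.io` without warnings: uniform
random simple graphs, Velvet-style LastGraph assemblies with implanted
bubbles, log-normal time-course tables, and presence/absence condition
frames that emulate per-condition molecular networks.
"""

from __future__ import annotations

import numpy as np

from .assembly import AssemblyArc, AssemblyGraph, AssemblyNode
from .errors import ParameterError
from .graph import Graph
from .io import TimeSeriesTable, write_lastgraph


def random_graph(n: int, m: int, seed: int = 0) -> Graph:
    """Uniform simple undirected graph with ``n`` nodes and ``m`` edges.

    Node ids are ``n001``-style zero-padded labels so lexicographic and
    numeric order agree.  Deterministic per seed.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    max_m = n * (n - 1) // 2
    if not (0 <= m <= max_m):
        raise ParameterError(f"m must lie in [0, {max_m}] for n={n}, got {m}")
    rng = np.random.default_rng(seed)
    width = max(3, len(str(n)))
    names = [f"n{i + 1:0{width}d}" for i in range(n)]
    g = Graph(directed=False)
    for name in names:
        g.add_node(name)
    chosen = rng.choice(max_m, size=m, replace=False)
    pairs = np.array(np.triu_indices(n, k=1)).T
    for idx in sorted(int(c) for c in chosen):
        a, b = pairs[idx]
        g.add_edge(names[int(a)], names[int(b)], "pp")
    return g


def synthetic_assembly(n_nodes: int, n_bubbles: int, seed: int = 0,
                       hash_length: int = 21) -> str:
    """LastGraph text for a backbone assembly with implanted bubbles.

    The graph is a linear backbone of contigs with ``n_bubbles`` diamond
    motifs implanted at spaced interior positions: each motif adds two
    variant nodes bridging one backbone junction, so the junction pair is
    joined by three unbranched paths (the backbone arc plus two two-arc
    detours) — exactly one bubble.  Remaining nodes become dangling decoy
    chains that never reconverge.  Arc orientations are drawn at random to
    exercise sign folding; multiplicities emulate read support.
    """
    if n_bubbles < 0:
        raise ParameterError("n_bubbles must be >= 0")
    remaining = n_nodes - 2 * n_bubbles
    n_decoys = max(0, remaining // 5)
    backbone_len = remaining - n_decoys
    # each bubble needs an interior backbone junction with 2 spare slots,
    # junctions spaced >= 2 apart to keep motifs independent
    if backbone_len < 4 or (n_bubbles > 0 and backbone_len < 2 * n_bubbles + 3):
        raise ParameterError(
            f"n_nodes={n_nodes} too small for {n_bubbles} bubbles")
    rng = np.random.default_rng(seed)

    arcs: list[tuple[int, int]] = []
    backbone = list(range(1, backbone_len + 1))
    for a, b in zip(backbone, backbone[1:]):
        arcs.append((a, b))

    junctions = rng.choice(np.arange(1, backbone_len - 1, 2), size=n_bubbles,
                           replace=False)
    next_id = backbone_len + 1
    for j in sorted(int(x) for x in junctions):
        s, t = backbone[j - 1], backbone[j]
        for _ in range(2):
            arcs.append((s, next_id))
            arcs.append((next_id, t))
            next_id += 1

    decoy_anchors = rng.integers(0, backbone_len, size=n_decoys)
    for anchor in decoy_anchors:
        arcs.append((backbone[int(anchor)], next_id))
        next_id += 1

    nodes = []
    for nid in range(1, next_id):
        length = int(rng.integers(5, 40))
        cov = float(rng.uniform(5.0, 60.0))
        seq1 = "".join(rng.choice(list("ACGT"), size=length))
        seq2 = "".join(rng.choice(list("ACGT"), size=length))
        nodes.append(AssemblyNode(nid, length, (round(cov, 2),), (seq1, seq2)))

    signed: list[AssemblyArc] = []
    for a, b in arcs:
        sa = int(a) * (1 if rng.random() < 0.5 else -1)
        sb = int(b) * (1 if rng.random() < 0.5 else -1)
        signed.append(AssemblyArc(sa, sb, int(rng.integers(1, 50))))

    asm = AssemblyGraph(nodes=nodes, arcs=signed, hash_length=hash_length,
                        sequence_count=int(rng.integers(100, 10000)))
    return write_lastgraph(asm)


def synthetic_timecourse(graph: Graph, n_frames: int, seed: int = 0,
                         sigma: float = 1.0) -> TimeSeriesTable:
    """Per-node log-normal values for each frame (expression/flux surrogate).

    Log-normal keeps values positive and right-skewed, the shape of
    abundance-like measurements; ``sigma`` is the log-scale spread.
    """
    if n_frames < 1:
        raise ParameterError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    labels = [f"t{i + 1}" for i in range(n_frames)]
    values = {nid: [float(v) for v in rng.lognormal(mean=0.0, sigma=sigma, size=n_frames)]
              for nid in sorted(graph.node_ids())}
    return TimeSeriesTable(labels, values)


def synthetic_frames(graph: Graph, n_frames: int, churn: float = 0.3,
                     seed: int = 0) -> list[Graph]:
    """Condition frames made by hiding a random ``churn`` fraction of the
    elements of ``graph`` per frame (MS-style presence/absence)."""
    if n_frames < 1:
        raise ParameterError("n_frames must be >= 1")
    if not (0.0 <= churn <= 1.0):
        raise ParameterError("churn must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    node_ids = sorted(graph.node_ids())
    frames: list[Graph] = []
    for _ in range(n_frames):
        hidden = {nid for nid in node_ids if rng.random() < churn}
        frame = graph.subgraph([n for n in node_ids if n not in hidden])
        # independently hide a churn fraction of the surviving edges
        for e in list(frame.edges()):
            if rng.random() < churn:
                frame.remove_edge(e.source, e.target, e.interaction)
        frames.append(frame)
    return frames
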