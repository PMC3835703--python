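"""Independent brute-force oracles used by the tests.

These deliberately avoid the code paths of the implementation they check:
bubble counting enumerates bounded walks per endpoint pair instead of
decomposing the graph into chains, and the force oracle is a plain double
loop over node pairs instead of vectorized array math.
"""

from __future__ import annotations

import math

from net3d.graph import Graph


def enumerate_unbranched_paths(graph: Graph, s: str, t: str, max_len: int) -> list[tuple[str, ...]]:
    """All simple s-t paths of <= max_len edges whose interior nodes all
    have degree exactly 2 (walks are forced once inside such a path)."""
    paths: list[tuple[str, ...]] = []
    for first in sorted(graph.neighbors(s)):
        walk = [s, first]
        while True:
            cur = walk[-1]
            if cur == t:
                paths.append(tuple(walk))
                break
            if graph.degree(cur) != 2 or len(walk) - 1 >= max_len or cur == s:
                break
            prev = walk[-2]
            nxt = next(iter(graph.neighbors(cur) - {prev}))
            if nxt in walk[1:]:
                break
            walk.append(nxt)
    return paths


def brute_force_bubbles(graph: Graph, max_len: int = 10) -> list[tuple[str, str]]:
    """All bubbles as (source, sink) pairs, by exhaustive pair enumeration.

    A pair qualifies when >= 2 distinct unbranched paths of <= max_len edges
    join it; qualifying pairs whose path-family node unions coincide (the
    symmetric endpoint choices around one cycle) collapse to a single
    report with the lexicographically smallest pair.
    """
    nodes = sorted(graph.node_ids())
    qualifying: dict[tuple[str, str], frozenset[str]] = {}
    for i, s in enumerate(nodes):
        for t in nodes[i + 1:]:
            paths = enumerate_unbranched_paths(graph, s, t, max_len)
            if len(paths) >= 2:
                union = frozenset(n for p in paths for n in p)
                qualifying[(s, t)] = union
    groups: dict[frozenset[str], tuple[str, str]] = {}
    for pair in sorted(qualifying):
        union = qualifying[pair]
        if union not in groups:
            groups[union] = pair
    return sorted(groups.values())


def brute_force_displacements(
    positions: dict[str, tuple[float, float, float]],
    edges: list[tuple[str, str]],
    k: float,
) -> dict[str, tuple[float, float, float]]:
    """Uncapped all-pairs spring-embedder forces by explicit double loop."""
    ids = list(positions)
    disp = {n: [0.0, 0.0, 0.0] for n in ids}
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            dx = [positions[a][c] - positions[b][c] for c in range(3)]
            d = math.sqrt(sum(x * x for x in dx))
            if d == 0:
                continue
            f = (k * k) / d
            for c in range(3):
                disp[a][c] += dx[c] / d * f
                disp[b][c] -= dx[c] / d * f
    for a, b in edges:
        if a == b:
            continue
        dx = [positions[a][c] - positions[b][c] for c in range(3)]
        d = math.sqrt(sum(x * x for x in dx))
        if d == 0:
            continue
        f = (d * d) / k
        for c in range(3):
            disp[a][c] -= dx[c] / d * f
            disp[b][c] += dx[c] / d * f
    return {n: tuple(v) for n, v in disp.items()}
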