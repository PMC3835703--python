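"""3D force-directed layout: spring embedder plus a multilevel scheme.

The embedder balances pairwise repulsion against edge attraction with the
classic spring-embedder magnitudes: repulsion ``k^2 / d`` between node pairs
and attraction ``d^2 / k`` along each edge, where ``k = C * (volume/n)**(1/3)``
is the ideal edge length in a 3D layout volume.  Per-iteration node
displacements are capped at a geometrically cooling temperature, so the
system anneals into a drawing with nearly equal edge lengths.  An isolated
connected pair is stationary exactly at distance ``k`` (the two magnitudes
cancel there), which the tests exploit as an analytic oracle.

All-pairs repulsion costs ``O(n^2)`` per sweep and is the default for the
single-level embedder.  For large graphs :func:`multilevel_layout` first
coarsens the network by collapsing a greedy maximal matching (recursively,
until at most ``coarsest_size`` supernodes remain), lays out the coarsest
graph exactly, then prolongs positions level by level, refining each with
repulsion restricted to a local neighborhood: a uniform spatial grid of cell
size equal to the cutoff radius (default ``2k``) supplies each node's nearby
candidates, and each node evaluates at most ``max_partners`` of them per
sweep.  The per-iteration number of repulsive pair evaluations is therefore
bounded by ``max_partners * n`` instead of ``n^2 / 2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .errors import GraphLookupError, NumericError, ParameterError
from .graph import Graph


@dataclass(frozen=True)
class LayoutParams:
    """Tunable layout constants.

    ``k = C * (volume / n) ** (1/3)``; with the defaults (``C = 1``,
    ``volume = n``) the ideal edge length is 1 in every graph.
    ``repulsion_radius=None`` means all-pairs repulsion; a positive number
    restricts repulsion to pairs within that distance via a spatial grid.
    """

    C: float = 1.0
    volume: float | None = None  # None -> n, so k = C
    iterations: int = 150
    initial_temperature: float | None = None  # None -> 0.1 * k * n**(1/3)
    cooling: float = 0.97
    repulsion_radius: float | None = None
    max_partners: int = 32
    coarsest_size: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.C <= 0 or (self.volume is not None and self.volume <= 0):
            raise ParameterError("C and volume must be positive")
        if self.iterations < 1 or self.coarsest_size < 1 or self.max_partners < 1:
            raise ParameterError("iterations, coarsest_size and max_partners must be >= 1")
        if not (0 < self.cooling < 1):
            raise ParameterError("cooling factor must lie in (0, 1)")
        if self.repulsion_radius is not None and self.repulsion_radius <= 0:
            raise ParameterError("repulsion_radius must be positive or None")

    def ideal_length(self, n: int) -> float:
        volume = self.volume if self.volume is not None else float(max(n, 1))
        return self.C * (volume / max(n, 1)) ** (1.0 / 3.0)

    def start_temperature(self, n: int) -> float:
        if self.initial_temperature is not None:
            return self.initial_temperature
        return 0.1 * self.ideal_length(n) * max(n, 1) ** (1.0 / 3.0)


@dataclass
class LayoutState:
    """A computed layout plus the bookkeeping that produced it."""

    positions: dict[str, tuple[float, float, float]]
    params: LayoutParams
    force_evaluations: int = 0
    max_evals_per_iteration: int = 0
    iterations_run: int = 0

    def as_array(self, order: Sequence[str]) -> np.ndarray:
        return np.array([self.positions[n] for n in order], dtype=float)


class Displacements(dict):
    """Node-id → 3D displacement mapping; ``evaluations`` counts the
    repulsive pairs examined while computing it."""

    evaluations: int = 0


# ------------------------------------------------------------------
# force kernel


def _repulsion_all_pairs(pos: np.ndarray, k: float, block: int = 1024
                         ) -> tuple[np.ndarray, int]:
    n = len(pos)
    disp = np.zeros_like(pos)
    for lo in range(0, n, block):
        hi = min(lo + block, n)
        diff = pos[lo:hi, None, :] - pos[None, :, :]          # (b, n, 3)
        d = np.linalg.norm(diff, axis=2)
        np.fill_diagonal(d[:, lo:hi], np.inf)
        d = np.maximum(d, 1e-12)
        disp[lo:hi] += np.einsum("ij,ijk->ik", (k * k) / (d * d), diff)
    return disp, n * (n - 1) // 2


def _grid_cells(pos: np.ndarray, cell: float) -> np.ndarray:
    idx = np.floor(pos / cell).astype(np.int64)
    return idx - idx.min(axis=0)


def _repulsion_grid(pos: np.ndarray, k: float, radius: float, max_partners: int,
                    rng: np.random.Generator) -> tuple[np.ndarray, int]:
    """Neighborhood-limited repulsion via a uniform grid with a per-node
    partner cap; evaluation count is bounded by ``max_partners * n``."""
    n = len(pos)
    disp = np.zeros_like(pos)
    cells = _grid_cells(pos, radius)
    dims = cells.max(axis=0) + 1
    cell_id = (cells[:, 0] * dims[1] + cells[:, 1]) * dims[2] + cells[:, 2]
    order = np.argsort(cell_id, kind="stable")
    sorted_ids = cell_id[order]
    uniq, starts = np.unique(sorted_ids, return_index=True)
    members = {cid: order[s:e] for cid, s, e in
               zip(uniq, starts, list(starts[1:]) + [n])}
    uniq_cells = {cid: cells[m[0]] for cid, m in members.items()}
    evals = 0
    for cid in uniq:
        mine = members[cid]
        cx, cy, cz = uniq_cells[cid]
        cand: list[np.ndarray] = []
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    nid = ((cx + dx) * dims[1] + (cy + dy)) * dims[2] + (cz + dz)
                    arr = members.get(nid)
                    if arr is not None and 0 <= cx + dx < dims[0] \
                            and 0 <= cy + dy < dims[1] and 0 <= cz + dz < dims[2]:
                        cand.append(arr)
        candidates = np.concatenate(cand)
        if len(candidates) <= max_partners + 1:
            partners = np.broadcast_to(candidates, (len(mine), len(candidates)))
        else:
            partners = candidates[rng.integers(0, len(candidates),
                                               size=(len(mine), max_partners))]
        diff = pos[mine][:, None, :] - pos[partners]           # (a, p, 3)
        d = np.linalg.norm(diff, axis=2)
        valid = (d > 1e-12) & (d <= radius)
        evals += partners.shape[0] * partners.shape[1]
        dsafe = np.where(valid, d, 1.0)
        w = np.where(valid, (k * k) / (dsafe * dsafe), 0.0)
        disp[mine] += np.einsum("ij,ijk->ik", w, diff)
    return disp, evals


def _attraction(pos: np.ndarray, edge_idx: np.ndarray, k: float) -> np.ndarray:
    disp = np.zeros_like(pos)
    if len(edge_idx) == 0:
        return disp
    diff = pos[edge_idx[:, 0]] - pos[edge_idx[:, 1]]
    d = np.maximum(np.linalg.norm(diff, axis=1), 1e-12)
    pull = (d / k)[:, None] * diff                             # (d^2/k) * diff/d
    np.add.at(disp, edge_idx[:, 0], -pull)
    np.add.at(disp, edge_idx[:, 1], pull)
    return disp


def _cap(disp: np.ndarray, temperature: float) -> np.ndarray:
    norm = np.linalg.norm(disp, axis=1)
    scale = np.where(norm > temperature, temperature / np.maximum(norm, 1e-300), 1.0)
    return disp * scale[:, None]


def _jitter_coincident(pos: np.ndarray, k: float, rng: np.random.Generator) -> np.ndarray:
    """Separate exactly coincident nodes by a tiny seeded offset."""
    _, inverse, counts = np.unique(pos, axis=0, return_inverse=True, return_counts=True)
    dup = counts[inverse] > 1
    if dup.any():
        pos = pos.copy()
        offsets = rng.standard_normal((int(dup.sum()), 3))
        offsets /= np.linalg.norm(offsets, axis=1, keepdims=True)
        pos[dup] += 1e-6 * k * offsets
    return pos


def compute_displacements(
    positions: dict[str, tuple[float, float, float]],
    edges: Iterable[tuple[str, str]],
    params: LayoutParams,
    temperature: float | None = None,
    rng: np.random.Generator | None = None,
) -> Displacements:
    """One force sweep: repulsion + attraction, optionally temperature-capped.

    ``edges`` lists endpoint id pairs; every endpoint must be positioned.
    The returned mapping carries ``evaluations``, the number of repulsive
    pairs examined.
    """
    order = list(positions)
    index = {nid: i for i, nid in enumerate(order)}
    pos = np.array([positions[nid] for nid in order], dtype=float)
    if pos.size and not np.isfinite(pos).all():
        bad = order[int(np.argwhere(~np.isfinite(pos))[0][0])]
        raise NumericError(f"non-finite coordinate for node {bad!r}")
    edge_idx_list = []
    for s, t in edges:
        if s not in index or t not in index:
            raise GraphLookupError(s if s not in index else t)
        if s != t:
            edge_idx_list.append((index[s], index[t]))
    edge_idx = np.array(edge_idx_list, dtype=int).reshape(-1, 2)
    rng = rng or np.random.default_rng(params.seed)
    n = len(order)
    k = params.ideal_length(n)
    pos = _jitter_coincident(pos, k, rng)
    if params.repulsion_radius is None:
        rep, evals = _repulsion_all_pairs(pos, k)
    else:
        rep, evals = _repulsion_grid(pos, k, params.repulsion_radius,
                                     params.max_partners, rng)
    disp = rep + _attraction(pos, edge_idx, k)
    if temperature is not None:
        disp = _cap(disp, temperature)
    result = Displacements((nid, tuple(disp[i])) for i, nid in enumerate(order))
    result.evaluations = evals
    return result


# ------------------------------------------------------------------
# single-level embedder


def _initial_positions(n: int, k: float, rng: np.random.Generator) -> np.ndarray:
    radius = k * n ** (1.0 / 3.0)
    v = rng.standard_normal((n, 3))
    v /= np.maximum(np.linalg.norm(v, axis=1, keepdims=True), 1e-12)
    return radius * v


def _anneal(pos: np.ndarray, edge_idx: np.ndarray, k: float, params: LayoutParams,
            t0: float, rng: np.random.Generator,
            radius: float | None) -> tuple[np.ndarray, int, int]:
    """Run the cooling loop in place; returns (pos, total_evals, max_per_iter)."""
    total = 0
    peak = 0
    t = t0
    for _ in range(params.iterations):
        pos = _jitter_coincident(pos, k, rng)
        if radius is None:
            rep, evals = _repulsion_all_pairs(pos, k)
        else:
            rep, evals = _repulsion_grid(pos, k, radius, params.max_partners, rng)
        disp = rep + _attraction(pos, edge_idx, k)
        pos = pos + _cap(disp, t)
        total += evals
        peak = max(peak, evals)
        t *= params.cooling
    return pos, total, peak


def _graph_arrays(graph: Graph) -> tuple[list[str], np.ndarray]:
    order = sorted(graph.node_ids())
    index = {nid: i for i, nid in enumerate(order)}
    seen = set()
    pairs = []
    for e in graph.edges():
        if e.source == e.target:
            continue
        key = (min(e.source, e.target), max(e.source, e.target))
        if key in seen:
            continue
        seen.add(key)
        pairs.append((index[e.source], index[e.target]))
    return order, np.array(pairs, dtype=int).reshape(-1, 2)


def fr_layout(graph: Graph, params: LayoutParams | None = None) -> LayoutState:
    """Single-level spring-embedder layout (all-pairs unless a radius is set).

    Deterministic for a fixed seed; the final drawing is centered at its
    centroid, so a single node lands at the origin.
    """
    params = params or LayoutParams()
    if graph.n_nodes == 0:
        raise ParameterError("cannot lay out an empty graph")
    order, edge_idx = _graph_arrays(graph)
    n = len(order)
    k = params.ideal_length(n)
    rng = np.random.default_rng(params.seed)
    pos = _initial_positions(n, k, rng)
    pos, total, peak = _anneal(pos, edge_idx, k, params,
                               params.start_temperature(n), rng, params.repulsion_radius)
    pos = pos - pos.mean(axis=0)
    return LayoutState(
        positions={nid: (float(pos[i, 0]), float(pos[i, 1]), float(pos[i, 2]))
                   for i, nid in enumerate(order)},
        params=params,
        force_evaluations=total,
        max_evals_per_iteration=peak,
        iterations_run=params.iterations,
    )


# ------------------------------------------------------------------
# multilevel scheme


@dataclass
class CoarseningLevel:
    """One coarsening step: the coarse graph plus fine→coarse parentage."""

    coarse_graph: Graph
    parent_map: dict[str, str] = field(default_factory=dict)


def coarsen(graph: Graph, seed: int | None = None) -> CoarseningLevel:
    """Collapse a greedy maximal matching into supernodes.

    Edges are visited in seeded-random order (id-sorted when ``seed`` is
    None); each matched pair becomes one supernode named after its smaller
    id, unmatched nodes pass through, self-loops vanish, and parallel coarse
    edges merge with summed ``weight``.
    """
    if graph.n_nodes < 2:
        raise ParameterError("coarsening needs at least 2 nodes")
    pairs = sorted({(min(e.source, e.target), max(e.source, e.target))
                    for e in graph.edges() if e.source != e.target})
    if seed is not None:
        rng = np.random.default_rng(seed)
        pairs = [pairs[i] for i in rng.permutation(len(pairs))]
    matched: set[str] = set()
    parent: dict[str, str] = {}
    for a, b in pairs:
        if a in matched or b in matched:
            continue
        matched.update((a, b))
        parent[a] = parent[b] = min(a, b)
    for nid in graph.node_ids():
        parent.setdefault(nid, nid)
    coarse = Graph(directed=False)
    for nid in graph.node_ids():
        coarse.add_node(parent[nid])
    weights: dict[tuple[str, str], float] = {}
    for e in graph.edges():
        ca, cb = parent[e.source], parent[e.target]
        if ca == cb:
            continue
        key = (min(ca, cb), max(ca, cb))
        weights[key] = weights.get(key, 0.0) + float(e.attributes.get("weight", 1.0))
    for (ca, cb), w in weights.items():
        coarse.add_edge(ca, cb, "coarse", weight=w)
    return CoarseningLevel(coarse_graph=coarse, parent_map=parent)


def prolong(
    level: CoarseningLevel,
    coarse_layout: LayoutState | dict[str, tuple[float, float, float]],
    jitter_radius: float,
    rng: np.random.Generator | None = None,
) -> dict[str, tuple[float, float, float]]:
    """Project coarse positions back to the fine graph.

    Each fine node lands at its parent's position plus a seeded-random
    offset of norm <= ``jitter_radius``; two siblings never coincide.
    """
    coarse_pos = coarse_layout.positions if isinstance(coarse_layout, LayoutState) else coarse_layout
    rng = rng or np.random.default_rng(0)
    fine_pos: dict[str, tuple[float, float, float]] = {}
    taken: dict[str, set[tuple[float, float, float]]] = {}
    for nid in sorted(level.parent_map):
        parent = level.parent_map[nid]
        if parent not in coarse_pos:
            raise GraphLookupError(parent)
        base = np.array(coarse_pos[parent], dtype=float)
        while True:
            direction = rng.standard_normal(3)
            direction /= max(np.linalg.norm(direction), 1e-12)
            offset = direction * jitter_radius * rng.random() ** (1.0 / 3.0)
            q = base + offset
            p = (float(q[0]), float(q[1]), float(q[2]))
            if p not in taken.setdefault(parent, set()):
                taken[parent].add(p)
                fine_pos[nid] = p
                break
    return fine_pos


def multilevel_layout(graph: Graph, params: LayoutParams | None = None) -> LayoutState:
    """Coarsen/layout/prolong/refine; identical to :func:`fr_layout` on
    graphs at or below ``coarsest_size`` nodes."""
    params = params or LayoutParams()
    if graph.n_nodes == 0:
        raise ParameterError("cannot lay out an empty graph")
    if graph.n_nodes <= params.coarsest_size:
        return fr_layout(graph, params)

    seeds = np.random.SeedSequence(params.seed)
    levels: list[CoarseningLevel] = []
    fine = graph
    while fine.n_nodes > params.coarsest_size:
        child_seed = int(seeds.spawn(1)[0].generate_state(1)[0] % (2**31))
        level = coarsen(fine, seed=child_seed)
        if level.coarse_graph.n_nodes >= fine.n_nodes:
            break  # no matchable edge left
        levels.append(level)
        fine = level.coarse_graph

    coarse_state = fr_layout(fine, replace(params, seed=int(
        seeds.spawn(1)[0].generate_state(1)[0] % (2**31))))
    positions = coarse_state.positions
    total = coarse_state.force_evaluations
    peak = coarse_state.max_evals_per_iteration
    iters = coarse_state.iterations_run

    for li in range(len(levels) - 1, -1, -1):
        level = levels[li]
        fine_graph = graph if li == 0 else levels[li - 1].coarse_graph
        n = len(level.parent_map)
        k = params.ideal_length(n)
        rng = np.random.default_rng(seeds.spawn(1)[0])
        positions = prolong(level, positions, jitter_radius=k / 4.0, rng=rng)
        order = sorted(positions)
        index = {nid: i for i, nid in enumerate(order)}
        fine_graph_edges = _unique_pairs(fine_graph)
        edge_idx = np.array([(index[a], index[b]) for a, b in fine_graph_edges],
                            dtype=int).reshape(-1, 2)
        pos = np.array([positions[nid] for nid in order], dtype=float)
        radius = params.repulsion_radius if params.repulsion_radius is not None else 2.0 * k
        pos, ev, pk = _anneal(pos, edge_idx, k, params, params.start_temperature(n),
                              rng, radius)
        total += ev
        peak = max(peak, pk)
        iters += params.iterations
        positions = {nid: (float(pos[i, 0]), float(pos[i, 1]), float(pos[i, 2]))
                     for i, nid in enumerate(order)}

    pos = np.array(list(positions.values()))
    centroid = pos.mean(axis=0)
    positions = {nid: (float(p[0] - centroid[0]), float(p[1] - centroid[1]),
                        float(p[2] - centroid[2])) for nid, p in positions.items()}
    return LayoutState(positions=positions, params=params, force_evaluations=total,
                       max_evals_per_iteration=peak, iterations_run=iters)


def _unique_pairs(g: Graph) -> set[tuple[str, str]]:
    """Unique undirected edge pairs of ``g`` (self-loops excluded)."""
    pairs = set()
    for e in g.edges():
        if e.source != e.target:
            pairs.add((min(e.source, e.target), max(e.source, e.target)))
    return pairs


# ------------------------------------------------------------------
# quality metrics


def layout_quality(graph: Graph,
                   layout: LayoutState | dict[str, tuple[float, float, float]]) -> dict[str, float]:
    """Edge-length mean and CV plus minimum pairwise node separation."""
    positions = layout.positions if isinstance(layout, LayoutState) else layout
    missing = [n for n in graph.node_ids() if n not in positions]
    if missing:
        raise GraphLookupError(missing[0])
    lengths = []
    for e in graph.edges():
        if e.source == e.target:
            continue
        a = np.array(positions[e.source])
        b = np.array(positions[e.target])
        lengths.append(float(np.linalg.norm(a - b)))
    mean = float(np.mean(lengths)) if lengths else math.nan
    cv = float(np.std(lengths) / mean) if lengths and mean > 0 else (0.0 if lengths else math.nan)
    pts = np.array([positions[n] for n in graph.node_ids()], dtype=float)
    if len(pts) < 2:
        min_sep = math.nan
    else:
        from scipy.spatial import cKDTree

        tree = cKDTree(pts)
        d, _ = tree.query(pts, k=2)
        min_sep = float(d[:, 1].min())
    return {"edge_length_mean": mean, "edge_length_cv": cv, "min_separation": min_sep}
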