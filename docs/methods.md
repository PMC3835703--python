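# Methods

This note records the models implemented in `net3d`, the parameter
defaults, and why they were chosen. Empirical numbers referenced here
are the ones computed by the test suite and by
`scripts/acceptance.py`; the package makes no performance or accuracy
claims beyond what those recompute.

## Graph model

A `Graph` is a set of string-identified nodes and a set of edges keyed
by `(source, target, interaction)`. Undirected graphs (the default)
canonicalize endpoint order, so `A–B` and `B–A` are the same edge;
directed mode keeps both orientations. Edges carry an interaction type
(SIF-style) and free-form attributes. The Cytoscape edge-identifier
convention `source (interaction) target` is used wherever an edge needs
a single string id (attribute tables, style maps, event payloads).

## 3D force-directed layout

### Single-level embedder

`fr_layout` implements Fruchterman–Reingold in three dimensions. With
ideal edge length

```
k = C · (volume / n)^(1/3)
```

every node pair repels with magnitude `k²/d` and every adjacent pair
attracts with `d²/k`, where `d` is the current Euclidean distance. Per
iteration, each node's net displacement is clamped to a temperature
that cools geometrically; initial positions are spread on a sphere of
radius `k · n^(1/3)`.

This model has analytic equilibria the tests pin down:

- an isolated connected pair is in equilibrium exactly at `d = k`
  (attraction `k²/k` equals repulsion `k²/k`);
- an isolated triangle is equilateral at equilibrium.

Coincident nodes (zero distance) are separated by a deterministic
seeded jitter of `1e-6·k` before forces are evaluated, so the sweep is
always finite.

### Defaults and why

| parameter | default | rationale |
|---|---|---|
| `C`, `volume` | `1.0`, `n` | makes `k = 1`, so distances read in units of the ideal edge length |
| `iterations` | `150` | see below |
| `cooling` | `0.97` | see below |
| `initial_temperature` | `0.1 · k · n^(1/3)` | a tenth of the initial sphere radius: large enough to escape the random start, small enough not to scatter converged structure |
| `max_partners` | `32` | bounds per-node repulsion work in neighborhood mode (see multilevel) |
| `coarsest_size` | `50` | a 50-node graph lays out all-pairs in negligible time |

The schedule (150 iterations, cooling 0.97) was chosen by measuring
layout quality on a 20-cycle, a shape whose ideal layout has uniform
edge lengths: shorter schedules (50 iterations, cooling 0.95) left an
edge-length coefficient of variation of up to 0.18 over seeds, while
150/0.97 stays below 0.10 (the acceptance script reports the measured
maximum). The cost on large graphs remains acceptable because per-node
work is bounded (next section).

### Multilevel scheme

For graphs above `coarsest_size` nodes:

1. **Coarsen** by greedy maximal matching over id-sorted edges: each
   matched pair collapses into a supernode named after its
   lexicographically smaller member; parallel coarse edges merge with
   summed weight; self-loops are dropped. Recurse until the coarse
   graph has at most `coarsest_size` nodes.
2. **Lay out** the coarsest graph with the all-pairs embedder.
3. **Prolong**: each fine node starts at its supernode's position plus
   a uniform-in-ball jitter of radius `k/4` (siblings are resampled if
   coincident).
4. **Refine** each level with the same force model, but repulsion is
   restricted to a geometric neighborhood: nodes are binned into a grid
   of cell size `2k`, partners are taken from the 27 surrounding cells
   within cutoff `2k`, and each node interacts with at most
   `max_partners` of them (a deterministic seeded sample when there are
   more). This caps repulsive force evaluations at `32·N` per
   iteration regardless of density — without the cap, a transiently
   collapsed region would make the grid method quadratic again.

Per-level random streams are derived with `numpy.random.SeedSequence.spawn`,
so results are bit-for-bit reproducible for a given seed, and a graph at
or below `coarsest_size` produces exactly the single-level layout.

The acceptance script lays out a 10,000-node / 250,000-edge random
graph and reports the peak repulsive evaluations per iteration (bounded
by construction at `32·N`) and the wall time (about 70 s on the
development machine; wall time is reported, not asserted, since it is
hardware-dependent).

## Assembly graphs and bubbles

`read_lastgraph` parses Velvet's `LastGraph`: a header
`node_count seq_count hash_length ...`, `NODE` blocks with two sequence
lines, and `ARC` lines whose node ids are orientation-signed.
`assembly_to_graph` folds orientation by default: arc endpoints `±a`
map to node `a`, and twin arcs describing the same junction on opposite
strands merge with summed multiplicity. (A `keep_orientation` mode
instead builds a directed graph on `a+`/`a−` strand nodes.)

A **bubble** is defined as an unordered node pair `(s, t)` joined by at
least two distinct paths of at most `max_path_len` edges (default 10)
whose interior nodes all have degree exactly 2. Interior-degree-2 makes
the paths automatically internally disjoint and matches the assembly
notion of unbranched variant sequences rejoining the backbone. On a
cycle, several endpoint pairs can qualify for what is visually one
bubble; qualifying pairs whose path families cover the same node set
are grouped, and one report is emitted per group with the
lexicographically smallest pair as representative. Under this
definition an isolated four-cycle ("diamond") is exactly one bubble.

The implementation decomposes the graph into unbranched chains anchored
at nodes of degree ≠ 2 (with separate handling for cycles attached to a
single anchor and for pure-cycle components), which is linear in the
graph size. The test suite checks it for exact agreement against an
independent brute-force enumerator (forced walks from every node pair)
on hundreds of seeded random and synthetic assembly graphs, and
cross-validates that enumerator against filtered
`networkx.all_simple_paths` on small graphs.

## Motion networks and animation

`build_motion_network` compiles an ordered list of condition frames
into the union graph plus, per frame, an id-sorted event list (edge
deletes, node deletes, node inserts, edge inserts) relative to the
previous frame. `replay(t)` folds the event lists and reproduces frame
`t` exactly — this invariant is asserted, not assumed.

`animate` renders all frames on a single layout of the union graph:
elements absent from a frame are omitted from that frame's scene rather
than moved, so shared elements have identical coordinates in every
frame. A time-course table (one numeric value per element per frame)
can drive node size, edge thickness, or a three-anchor color ramp;
values map affinely onto the style range per frame, with a constant
frame mapping to the range midpoint.

## Scene synchronization

A scene (graph, positions, style maps, highlight set) is synchronized
by an ordered event stream. `diff(old, new)` emits structural events
first, then style updates sorted by element and channel; `apply`
replays events strictly in sequence order, validating that sequence
numbers increase, that inserts do not collide, and that style events
refer to live elements. The contract `apply(x, diff(x, y)) == y` (and
`diff(x, x) == []`) is property-tested over random scene pairs. When an
element is deleted, its style entries are shed at the delete event —
important when one applied batch spans a delete and a later reinsert.

A `SyncSession` owns the authoritative scene and assigns strictly
increasing sequence numbers; clients join by snapshot (scene JSON, see
`docs/protocol.md`) and then consume deltas, which requires the
snapshot serialization to be lossless — unset style channels are
omitted, never filled with defaults. The TCP transport broadcasts
newline-delimited JSON; the same logic is exercised in-process by
`LocalMirror` for deterministic tests.

## Synthetic generators

The generators exist to produce seeded, text-only inputs with known
ground truth; they are deliberately simple and are not claimed to be
statistically realistic:

- `random_graph(n, m, seed)` — uniform over simple graphs with exactly
  `n` nodes and `m` edges.
- `synthetic_assembly(n_nodes, n_bubbles, seed)` — a backbone path with
  each implanted bubble replacing one backbone edge by a direct arc
  plus two two-arc detours (so each bubble has exactly three parallel
  paths), plus a few decoy leaf nodes; arcs get random signs and
  multiplicities, nodes random sequences. Ground truth: exactly
  `n_bubbles` bubbles.
- `synthetic_timecourse` — independent log-normal values per element
  and frame (positive, right-skewed, like abundance data).
- `synthetic_frames` — hides a `churn` fraction of nodes, then of
  surviving edges, per frame; ground truth: every frame is a subgraph
  of the base.

## Numerical choices

- All randomness goes through `numpy.random.default_rng` /
  `SeedSequence`; identical seeds give bit-identical outputs.
- Layout positions are plain Python floats (JSON-safe) in the public
  API; internals use float64 arrays.
- Colors are float RGB triples in `[0, 1]`; hex conversion exists for
  display but serialization keeps full precision.
- Force sweeps are vectorized; the all-pairs path is checked against an
  explicit double loop at `1e-9` per coordinate.

## Limitations

- Bubble detection reports one representative pair per path-family
  group; on a cycle hanging off a single hub the representative is the
  lexicographically smallest qualifying pair, which need not be the
  visually "widest" one.
- The neighborhood repulsion approximation (cutoff `2k`, at most 32
  partners) trades global untangling force for bounded work; very dense
  or pathological graphs may need more refinement iterations.
- The sync server trusts its clients and uses no authentication or
  encryption; it is meant for localhost or trusted-network viewers.
- The LastGraph reader preserves but does not interpret short-read
  tracking records (`NR`/`SEQ` blocks).
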