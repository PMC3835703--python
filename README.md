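# net3d

Tools for building, laying out, animating, and synchronizing 3D views of
biological networks: protein/metabolite interaction graphs, genome
assembly graphs, and time-resolved "motion networks" whose topology
changes from frame to frame.

## What it does

Large biological networks are hard to read in 2D: layouts of a few
thousand nodes collapse into hairballs, and processes that unfold over
time (metabolic flux across growth phases, contig graphs from different
samples) don't fit a single static picture. `net3d` addresses this with
four pieces:

- **3D force-directed layout.** A Fruchterman–Reingold embedder in three
  dimensions: nodes repel with force `k²/d`, adjacent nodes attract with
  `d²/k`, where `k` is the ideal edge length and `d` the current
  distance. Displacements are capped by a geometrically cooling
  temperature. For large graphs a multilevel scheme coarsens the graph
  by greedy edge matching, lays out the small coarse graph, then
  prolongs and refines level by level using a grid-bounded neighborhood
  approximation, so per-iteration work stays linear in the node count.
- **Assembly-graph analysis.** A reader for Velvet's `LastGraph` format,
  orientation folding into an undirected contig graph, and a *bubble*
  detector: pairs of nodes joined by two or more unbranched paths
  (interior nodes of degree exactly 2), the signature of allelic or
  repeat-induced variation in an assembly.
- **Motion networks.** A sequence of condition/time frames is compiled
  into a union graph plus ordered mutation events (insert/delete of
  nodes and edges). Frames replay exactly, and animations render on one
  fixed union-graph layout so shared elements never jump between frames.
  Time-course tables can drive node size, edge thickness, or a color
  ramp.
- **Scene synchronization.** A scene (graph + positions + visual style)
  can be diffed into an ordered event stream and rebuilt by applying it
  (`apply(x, diff(x, y)) == y`). A small TCP server broadcasts a scene
  as newline-delimited JSON — snapshot on join, deltas afterwards — so
  several viewers converge on the same state.

See `docs/methods.md` for the model and parameter choices and
`docs/protocol.md` for the scene-JSON and wire formats.

## Worked example

Generate a synthetic assembly graph with three implanted bubbles, find
them, and lay the graph out:

```sh
net3d fixtures --kind assembly --n 30 --bubbles 3 --seed 7 --out asm.lastgraph
net3d convert --lastgraph asm.lastgraph --out asm.sif
net3d bubbles --input asm.sif --out bubbles.tsv
net3d layout --input asm.sif --seed 7 --out asm_layout.json
```

`bubbles.tsv` then contains exactly the three implanted bubbles:

```text
source	sink	n_paths	paths
11	12	3	11|12;11|21|12;11|22|12
13	14	3	13|14;13|23|14;13|24|14
17	18	3	17|18;17|25|18;17|26|18
```

The same pieces are available as a library:

```python
from net3d import (LayoutParams, assembly_to_graph, detect_bubbles,
                   multilevel_layout, read_lastgraph)

asm = read_lastgraph(open("asm.lastgraph").read())
graph = assembly_to_graph(asm)          # orientation-folded, undirected
for b in detect_bubbles(graph):
    print(b.source, b.sink, b.n_paths)

state = multilevel_layout(graph, LayoutParams(seed=7))
state.positions["11"]                   # -> (x, y, z)
```

Layouts are deterministic per seed (bit-for-bit across runs) and respect
the model's analytic equilibria: an isolated connected pair settles at
distance `k` to within 0.3%, and an equilateral triangle's edge-length
coefficient of variation is at machine precision (numbers from
`results/acceptance.json`, seed 1).

Animate six condition frames on a shared layout:

```sh
net3d fixtures --kind frames --n 20 --m 35 --frames 6 --seed 4 --out frames/
net3d animate --frames frames/frame1.sif,frames/frame2.sif,frames/frame3.sif,frames/frame4.sif,frames/frame5.sif,frames/frame6.sif --seed 4 --out anim.json
```

Serve a scene to mirroring viewers:

```sh
net3d layout --input asm.sif --seed 7 --out scene.json
net3d serve --input scene.json --port 20738 &
net3d mirror --host 127.0.0.1 --port 20738 --out mirrored.json
```

## Repository layout

- `src/net3d/` — the package (`graph`, `io`, `layout`, `assembly`,
  `dynamics`, `sync`, `fixtures`, `cli`)
- `tests/` — pytest suite; `tests/test_acceptance.py` holds one
  end-to-end test per acceptance criterion, and `tests/_oracles.py` the
  independent brute-force oracles
- `docs/methods.md` — model, parameters, and their rationale
- `docs/protocol.md` — scene JSON schema and the sync wire format
- `scripts/acceptance.py` — standalone reproduction script
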