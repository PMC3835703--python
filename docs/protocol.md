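# Scene JSON and the sync wire protocol

## Scene JSON (schema version 1)

A *scene* is a renderable snapshot: a graph, one 3D position per node,
and optional visual style. `net3d.io.export_scene` /
`net3d.io.import_scene` read and write this format; the `layout` CLI
command emits it, and the sync protocol uses it as its join snapshot.

```json
{
  "schema": 1,
  "directed": false,
  "nodes": [
    {
      "id": "n001",
      "x": 0.12, "y": -1.4, "z": 0.7,
      "label": false,
      "attributes": {},
      "size": 22.5,
      "color": [0.1, 0.1, 0.9]
    }
  ],
  "edges": [
    {
      "source": "n001",
      "target": "n002",
      "interaction": "pp",
      "attributes": {},
      "thickness": 2.0,
      "color": [0.6, 0.6, 0.6]
    }
  ]
}
```

Rules:

- `id`, `x`, `y`, `z`, `label` (highlight flag), and `attributes` are
  always present per node; `source`, `target`, `interaction`,
  `attributes` per edge.
- `size`, `thickness`, and `color` are **optional** and appear only
  when that style channel is explicitly set. Absent means "renderer
  default". This keeps `import_scene(export_scene(s)) == s` exact,
  which the sync join protocol depends on.
- Colors are RGB float triples in `[0, 1]` (full precision, no hex
  quantization).
- Nodes and edges are sorted by id, keys are sorted, so equal scenes
  serialize to identical bytes.
- An animation (`export_scene_sequence`) is a JSON array of these
  objects, one per frame, in frame order.

## Mutation events

All change propagation uses one event record (`MutationEvent`):

```json
{"seq": 7, "kind": "update", "target": "style",
 "payload": {"element": "n001", "channel": "size", "value": 22.5}}
```

- `seq` — server-assigned, strictly increasing integer.
- `kind` — `insert` | `delete` | `update`.
- `target` — `node` | `edge` | `style`.
- `payload` for nodes: `{"id": ..., "attributes": {...}}`; for edges:
  `{"source": ..., "target": ..., "interaction": ..., "attributes": {...}}`;
  for styles: `{"element": <node id or "src (interaction) tgt" edge id>,
  "channel": ..., "value": ...}` (no `value` on delete).
- Style channels: `position` (3-float list), `size` (float),
  `node_color` / `edge_color` (3-float list), `thickness` (float),
  `highlight` (bool).

Within one commit, events are ordered: edge deletes, node deletes, node
inserts, edge inserts, then style updates sorted by element id and
channel. Receivers must apply events strictly in `seq` order; deleting
an element discards its style entries.

## TCP wire format

The server (`net3d serve`, default port 20738) speaks newline-delimited
JSON (UTF-8, one object per line) over TCP:

1. On connect the client receives a snapshot frame:

   ```json
   {"type": "snapshot", "scene": { ...scene JSON object... }, "last_seq": 41}
   ```

2. Afterwards the server pushes one frame per event, in order:

   ```json
   {"type": "event", "seq": 42, "kind": "delete", "target": "node",
    "payload": {"id": "n003"}}
   ```

The client imports the snapshot, then applies each event with
`net3d.sync.apply`. Clients joining at different times converge: a
snapshot at `last_seq = n` plus events `> n` produces the same scene as
any earlier snapshot plus the full stream. The transport is one-way
(server to client) and unauthenticated; run it on localhost or a
trusted network.
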