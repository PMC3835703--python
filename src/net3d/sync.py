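"""Multi-client scene synchronization.

One process owns the scene; any number of read-only clients mirror it.  All
changes travel as ordered :class:`~net3d.dynamics.MutationEvent` records:
structural deletions first, then insertions, then style updates, each block
sorted by element id, with server-assigned, strictly increasing sequence
numbers.  ``apply(scene, diff(old, new))`` reproduces ``new`` exactly, so
every client that consumed the same event stream holds an identical scene.

The wire format is newline-delimited JSON over a plain TCP socket: a joining
client first receives a full-state snapshot (the scene-JSON document plus
the server's current sequence number), then incremental event records.  A
client that reconnects simply receives a fresh snapshot.  The schema is
documented in ``docs/protocol.md``.
"""

from __future__ import annotations

import json
import socket
import socketserver
import threading
from typing import Iterable, Sequence

from .dynamics import MutationEvent, apply_graph_events, diff_graphs
from .errors import SyncError
from .graph import Scene, edge_id
from .io import export_scene, import_scene

_STYLE_CHANNELS = ("position", "size", "node_color", "thickness", "edge_color", "highlight")


def _style_maps(scene: Scene) -> dict[str, dict]:
    return {
        "position": scene.positions,
        "size": scene.node_size,
        "node_color": scene.node_color,
        "thickness": scene.edge_thickness,
        "edge_color": scene.edge_color,
    }


def _jsonable(value):
    if isinstance(value, tuple):
        return list(value)
    return value


def diff(old: Scene, new: Scene, seq_start: int = 0) -> list[MutationEvent]:
    """Minimal ordered event set transforming ``old`` into ``new``.

    ``diff(x, x)`` is empty.  Structural graph events come first (see
    :func:`~net3d.dynamics.diff_graphs`), then style updates sorted by
    element id and channel.  Style entries of structurally deleted elements
    are dropped implicitly by :func:`apply`.
    """
    events = diff_graphs(old.graph, new.graph, seq_start=seq_start)
    seq = seq_start + len(events)
    style_events: list[tuple[str, str, MutationEvent]] = []

    old_maps, new_maps = _style_maps(old), _style_maps(new)
    surviving_nodes = set(new.graph.node_ids())
    surviving_edges = {e.id for e in new.graph.edges()}
    for channel in ("position", "size", "node_color", "thickness", "edge_color"):
        om, nm = old_maps[channel], new_maps[channel]
        alive = surviving_edges if channel in ("thickness", "edge_color") else surviving_nodes
        for eid in set(om) | set(nm):
            if eid not in alive:
                continue  # element removed structurally; styles go with it
            if eid in nm and om.get(eid) != nm[eid]:
                style_events.append((eid, channel, MutationEvent(
                    0, "update", "style",
                    {"element": eid, "channel": channel, "value": _jsonable(nm[eid])})))
            elif eid in om and eid not in nm:
                style_events.append((eid, channel, MutationEvent(
                    0, "delete", "style", {"element": eid, "channel": channel})))
    for nid in sorted((old.highlighted ^ new.highlighted) & surviving_nodes):
        style_events.append((nid, "highlight", MutationEvent(
            0, "update", "style",
            {"element": nid, "channel": "highlight", "value": nid in new.highlighted})))

    for eid, channel, ev in sorted(style_events, key=lambda x: (x[0], x[1])):
        ev.seq = seq
        seq += 1
        events.append(ev)
    return events


def apply(scene: Scene, events: Iterable[MutationEvent],
          last_seq: int | None = None) -> Scene:
    """Apply an ordered event batch to a copy of ``scene``.

    Sequence numbers must strictly increase and, when ``last_seq`` is
    given, start above it; a stale or out-of-order event raises
    :class:`SyncError`, as does inserting an element that already exists.
    """
    events = list(events)
    prev = last_seq
    for ev in events:
        if prev is not None and ev.seq <= prev:
            raise SyncError("stale or out-of-order event", seq=ev.seq)
        prev = ev.seq

    out = scene.copy()
    maps = _style_maps(out)
    # events are applied strictly in order: a batch may span several commits,
    # so a delete/reinsert pair must shed the element's styles in between
    for ev in events:
        if ev.target in ("node", "edge"):
            try:
                out.graph = apply_graph_events(out.graph, [ev])
            except Exception as exc:  # conflicting structural event
                raise SyncError(str(exc), seq=ev.seq) from exc
            if ev.kind == "delete":
                if ev.target == "node":
                    nid = ev.payload["id"]
                    for mapping in (out.positions, out.node_size, out.node_color):
                        mapping.pop(nid, None)
                    out.highlighted.discard(nid)
                else:
                    eid = edge_id(ev.payload["source"], ev.payload["target"],
                                  ev.payload.get("interaction", "pp"))
                    out.edge_thickness.pop(eid, None)
                    out.edge_color.pop(eid, None)
            continue
        eid = ev.payload["element"]
        channel = ev.payload["channel"]
        if channel not in _STYLE_CHANNELS:
            raise SyncError(f"unknown style channel {channel!r}", seq=ev.seq)
        if channel in ("thickness", "edge_color"):
            alive = {e.id for e in out.graph.edges()}
        else:
            alive = set(out.graph.node_ids())
        if eid not in alive:
            raise SyncError(f"style event for absent element {eid!r}", seq=ev.seq)
        if channel == "highlight":
            if ev.kind == "delete" or not ev.payload.get("value", False):
                out.highlighted.discard(eid)
            else:
                out.highlighted.add(eid)
            continue
        mapping = maps[channel]
        if ev.kind == "delete":
            mapping.pop(eid, None)
        else:
            value = ev.payload["value"]
            if isinstance(value, list):
                value = tuple(value)
            mapping[eid] = value
    return out


# ------------------------------------------------------------------
# transports


class SyncSession:
    """In-process hub: owns the authoritative scene and the event log."""

    def __init__(self, scene: Scene):
        self.scene = scene.copy()
        self.log: list[MutationEvent] = []
        self._lock = threading.Lock()

    @property
    def last_seq(self) -> int:
        return self.log[-1].seq if self.log else -1

    def update(self, new_scene: Scene) -> list[MutationEvent]:
        """Diff the current scene against ``new_scene``, commit, broadcast."""
        with self._lock:
            events = diff(self.scene, new_scene, seq_start=self.last_seq + 1)
            self.scene = apply(self.scene, events, last_seq=self.last_seq)
            self.log.extend(events)
            return events

    def snapshot(self) -> tuple[str, int]:
        with self._lock:
            return export_scene(self.scene), self.last_seq

    def events_after(self, seq: int) -> list[MutationEvent]:
        with self._lock:
            return [ev for ev in self.log if ev.seq > seq]


class LocalMirror:
    """A read-only in-process client: snapshot at join, then deltas."""

    def __init__(self, session: SyncSession):
        self._session = session
        text, self.last_seq = session.snapshot()
        self.scene = import_scene(text)

    def pull(self) -> int:
        """Consume pending events; returns how many were applied."""
        events = self._session.events_after(self.last_seq)
        if events:
            self.scene = apply(self.scene, events, last_seq=self.last_seq)
            self.last_seq = events[-1].seq
        return len(events)


class _Handler(socketserver.StreamRequestHandler):
    def handle(self) -> None:  # pragma: no cover - exercised via sockets
        server: SceneServer = self.server  # type: ignore[assignment]
        snapshot, last_seq = server.session.snapshot()
        self.wfile.write((json.dumps(
            {"type": "snapshot", "scene": json.loads(snapshot), "last_seq": last_seq},
            sort_keys=True) + "\n").encode())
        self.wfile.flush()
        sent = last_seq
        while not server.closing.is_set():
            events = server.session.events_after(sent)
            for ev in events:
                self.wfile.write((json.dumps(
                    {"type": "event", **ev.to_json()}, sort_keys=True) + "\n").encode())
                sent = ev.seq
            self.wfile.flush()
            server.wakeup.wait(timeout=0.05)


class SceneServer(socketserver.ThreadingTCPServer):
    """Broadcasts a :class:`SyncSession` over newline-delimited JSON / TCP."""

    allow_reuse_address = True
    daemon_threads = True

    def __init__(self, session: SyncSession, host: str = "127.0.0.1", port: int = 0):
        self.session = session
        self.closing = threading.Event()
        self.wakeup = threading.Event()
        super().__init__((host, port), _Handler)
        self._thread: threading.Thread | None = None

    @property
    def address(self) -> tuple[str, int]:
        return self.server_address  # type: ignore[return-value]

    def start(self) -> None:
        self._thread = threading.Thread(target=self.serve_forever, daemon=True)
        self._thread.start()

    def publish(self, new_scene: Scene) -> list[MutationEvent]:
        events = self.session.update(new_scene)
        self.wakeup.set()
        self.wakeup.clear()
        return events

    def stop(self) -> None:
        self.closing.set()
        self.shutdown()
        self.server_close()
        if self._thread is not None:
            self._thread.join(timeout=5)


def serve(scene: Scene, host: str = "127.0.0.1", port: int = 0) -> SceneServer:
    """Start broadcasting ``scene``; returns the running server."""
    server = SceneServer(SyncSession(scene), host, port)
    server.start()
    return server


def subscribe(host: str, port: int, until_seq: int | None = None,
              timeout: float = 10.0) -> Scene:
    """Join a running server and mirror its scene.

    Receives the snapshot, then applies events until ``until_seq`` is
    reached (or, when None, until the stream goes quiet past the snapshot
    sequence).  Returns the mirrored scene.
    """
    with socket.create_connection((host, port), timeout=timeout) as sock:
        sock.settimeout(timeout)
        reader = sock.makefile("r", encoding="utf-8")
        first = json.loads(reader.readline())
        if first.get("type") != "snapshot":
            raise SyncError("server did not open with a snapshot")
        scene = import_scene(json.dumps(first["scene"]))
        last_seq = int(first["last_seq"])
        target = until_seq if until_seq is not None else last_seq
        while last_seq < target:
            line = reader.readline()
            if not line:
                raise SyncError("server closed before reaching target sequence")
            record = json.loads(line)
            if record.get("type") != "event":
                continue
            ev = MutationEvent.from_json(record)
            scene = apply(scene, [ev], last_seq=last_seq)
            last_seq = ev.seq
        return scene
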