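"""Reversible edit provenance for multilayer graphs.

A :class:`View` pairs a deep snapshot of a graph (``original``) with a
working copy (``current``) and the ordered list of modification steps between
them.  Every step records enough restoration payload to invert itself in
isolation, so :func:`undo` can walk the most recent ``n`` steps backwards and
restore the earlier state exactly — undoing a node deletion re-adds the node,
all its incident edges, and removes any transitive edges that the deletion
spawned; undoing a layer deletion restores the layer, its nodes and all their
connections in one step.

Steps are atomic: a failed operation leaves both the graph and the step list
untouched.  Step ids continue after undo rather than resetting, so an audit
trail is never ambiguous; undone steps are kept in an internal audit log that
is persisted alongside the view (there is no redo).
"""

from __future__ import annotations

import json
import uuid
from dataclasses import dataclass, field
from datetime import datetime, timezone

from .core import MultilayerGraph, graphs_equal
from .errors import ArgumentError, FormatError, UnknownEdgeError

_VALID_ACTIONS = {"add", "remove"}
_VALID_ELEMENTS = {"node", "edge", "layer"}


def _utcnow() -> str:
    return datetime.now(timezone.utc).isoformat()


@dataclass
class Step:
    """One recorded modification with its inversion payload."""

    step_id: int
    action: str
    element: str
    name: str
    payload: dict
    timestamp: str

    def to_obj(self) -> dict:
        return {
            "step_id": self.step_id,
            "action": self.action,
            "element": self.element,
            "name": self.name,
            "payload": self.payload,
            "timestamp": self.timestamp,
        }

    @classmethod
    def from_obj(cls, obj: dict) -> "Step":
        return cls(
            obj["step_id"], obj["action"], obj["element"], obj["name"], obj["payload"], obj["timestamp"]
        )


class View:
    """Provenance record: original snapshot, current graph, ordered steps."""

    def __init__(self, graph: MultilayerGraph, clock=None, view_id: str | None = None):
        self._clock = clock or _utcnow
        self.view_id = view_id or uuid.uuid4().hex[:12]
        self.created_at = self._clock()
        self.last_modified_at = self.created_at
        self.original = graph.copy()
        self.current = graph.copy()
        self.steps: list[Step] = []
        self.audit: list[dict] = []  # undone steps, for transparency
        self._next_step_id = 1


def create_view(graph: MultilayerGraph, clock=None) -> View:
    """Snapshot a graph into a fresh view; later mutation of ``graph`` does
    not affect the view."""
    return View(graph, clock=clock)


# ----------------------------------------------------------------- apply / invert
def _apply(g: MultilayerGraph, action: str, element: str, name: str, extra: dict) -> dict:
    """Apply one operation to ``g`` and return its inversion payload."""
    if action not in _VALID_ACTIONS:
        raise ArgumentError(f"action must be add or remove, got {action!r}")
    if element not in _VALID_ELEMENTS:
        raise ArgumentError(f"element must be node, edge or layer, got {element!r}")

    if element == "layer":
        if action == "add":
            lid = g.add_layer(name)
            return {"layer_id": lid, "layer_name": name}
        lid = g.layer_id(name)
        nodes, edges, trans = g.remove_layer(name, transitive=bool(extra.get("transitive", False)))
        return {
            "layer_id": lid,
            "layer_name": name,
            "removed_nodes": [n.to_obj() for n in nodes],
            "removed_edges": [e.to_obj() for e in edges],
            "added_transitive": [e.to_obj() for e in trans],
        }

    if element == "node":
        if action == "add":
            node = g.add_node(name, extra["layer"], dict(extra.get("attributes", {})))
            return {"node": node.to_obj()}
        node = g.get_node(name)
        removed, trans = g.remove_node(name, transitive=bool(extra.get("transitive", False)))
        return {
            "node": node.to_obj(),
            "removed_edges": [e.to_obj() for e in removed],
            "added_transitive": [e.to_obj() for e in trans],
        }

    # element == "edge"
    a, b = extra["a"], extra["b"]
    if action == "add":
        edge = g.add_edge(a, b, dict(extra.get("attributes", {})))
        return {"edge": edge.to_obj()}
    removed = g.remove_edge(a, b, extra.get("key", "all"))
    return {"removed_edges": [e.to_obj() for e in removed]}


def _invert(g: MultilayerGraph, step: Step) -> None:
    p = step.payload
    if step.element == "layer":
        if step.action == "add":
            g.remove_layer(p["layer_name"], transitive=False)
            # inversion runs in strict reverse order, so the id counter can be
            # rolled back to its exact pre-step value
            g._next_layer_id = p["layer_id"]
            return
        lid = p.get("layer_id")
        if lid is None and p["removed_nodes"]:
            lid = p["removed_nodes"][0]["layer_id"]
        g._restore_layer(lid, p["layer_name"]) if lid is not None else g.add_layer(p["layer_name"])
        _restore_nodes_edges(g, p)
        return
    if step.element == "node":
        if step.action == "add":
            g.remove_node(p["node"]["name"], transitive=False)
            return
        n = p["node"]
        g.add_node(n["name"], n["layer_name"], dict(n["attributes"]))
        _restore_nodes_edges(g, p, skip_nodes=True)
        return
    # edge
    if step.action == "add":
        e = p["edge"]
        g.remove_edge(e["a"], e["b"], e["key"])
        return
    for eo in p["removed_edges"]:
        g.add_edge(eo["a"], eo["b"], dict(eo["attributes"]), key=eo["key"])


def _restore_nodes_edges(g: MultilayerGraph, payload: dict, skip_nodes: bool = False) -> None:
    if not skip_nodes:
        for no in payload.get("removed_nodes", []):
            g.add_node(no["name"], no["layer_name"], dict(no["attributes"]))
    for eo in payload.get("removed_edges", []):
        g.add_edge(eo["a"], eo["b"], dict(eo["attributes"]), key=eo["key"])
    for eo in payload.get("added_transitive", []):
        try:
            g.remove_edge(eo["a"], eo["b"], eo["key"])
        except UnknownEdgeError:
            # a spawned transitive edge can only be absent if the payload is
            # inconsistent with the state; surface it rather than hide it
            raise


# ------------------------------------------------------------------------ steps
def add_step(view: View, action: str, element: str, name: str, extra: dict | None = None) -> View:
    """Apply one modification to ``view.current`` and record it as a step.

    ``extra`` carries element-specific arguments: ``layer`` and
    ``attributes`` for node addition, ``a``/``b`` (and ``attributes`` or
    ``key``) for edge operations, ``transitive`` for removals.  A layer
    removal is one step no matter how many nodes and edges it deletes.
    On error nothing is recorded and the graph is unchanged.
    """
    extra = dict(extra or {})
    work = view.current.copy()
    payload = _apply(work, action, element, name, extra)  # may raise; view untouched
    view.current = work
    step = Step(view._next_step_id, action, element, name, payload, view._clock())
    view._next_step_id += 1
    view.steps.append(step)
    view.last_modified_at = step.timestamp
    return view


def undo(view: View, n_steps: int) -> View:
    """Invert the latest ``n_steps`` steps in reverse order and drop them
    from the step list (they move to the audit log)."""
    if not isinstance(n_steps, int) or not 1 <= n_steps <= len(view.steps):
        raise ArgumentError(f"n_steps must be between 1 and {len(view.steps)}, got {n_steps!r}")
    work = view.current.copy()
    for step in reversed(view.steps[-n_steps:]):
        _invert(work, step)
    view.current = work
    dropped = view.steps[-n_steps:]
    view.steps = view.steps[:-n_steps]
    view.audit.extend({"undone_at": view._clock(), **s.to_obj()} for s in dropped)
    view.last_modified_at = view._clock()
    return view


# ------------------------------------------------------------------ inspection
def view_summary(view: View) -> str:
    """Human-readable transformation trail of the view."""
    l0, n0, e0 = view.original.shape()
    l1, n1, e1 = view.current.shape()
    lines = [
        f"view {view.view_id}",
        f"  created:  {view.created_at}",
        f"  modified: {view.last_modified_at}",
        f"  original: {l0} layers, {n0} nodes, {e0} edges",
        f"  current:  {l1} layers, {n1} nodes, {e1} edges",
        f"  {len(view.steps)} steps",
    ]
    for s in view.steps:
        counts = ""
        p = s.payload
        if s.action == "remove":
            nn = len(p.get("removed_nodes", [])) + (1 if "node" in p else 0)
            ne = len(p.get("removed_edges", []))
            nt = len(p.get("added_transitive", []))
            counts = f" (-{nn} nodes, -{ne} edges, +{nt} transitive)"
        lines.append(f"  [{s.step_id}] {s.action} {s.element} {s.name!r}{counts}")
    return "\n".join(lines)


def views_equal(v1: View, v2: View) -> bool:
    """Equality used in tests: equal graphs and equal step records."""
    return (
        graphs_equal(v1.original, v2.original)
        and graphs_equal(v1.current, v2.current)
        and [s.to_obj() for s in v1.steps] == [s.to_obj() for s in v2.steps]
    )


# ----------------------------------------------------------------- persistence
def save_view(view: View, path: str) -> str:
    """Persist the full view (both graphs, steps, audit log) as one JSON file."""
    obj = {
        "view_id": view.view_id,
        "created_at": view.created_at,
        "last_modified_at": view.last_modified_at,
        "next_step_id": view._next_step_id,
        "original": view.original.to_obj(),
        "current": view.current.to_obj(),
        "steps": [s.to_obj() for s in view.steps],
        "audit": view.audit,
    }
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1)
    return path


def load_view(path: str, clock=None) -> View:
    try:
        with open(path) as fh:
            obj = json.load(fh)
        view = View.__new__(View)
        view._clock = clock or _utcnow
        view.view_id = obj["view_id"]
        view.created_at = obj["created_at"]
        view.last_modified_at = obj["last_modified_at"]
        view._next_step_id = obj["next_step_id"]
        view.original = MultilayerGraph.from_obj(obj["original"])
        view.current = MultilayerGraph.from_obj(obj["current"])
        view.steps = [Step.from_obj(s) for s in obj["steps"]]
        view.audit = list(obj.get("audit", []))
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise FormatError(f"not a valid view file: {exc}") from exc
    return view
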