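"""Multilayer attributed multigraph.

A :class:`MultilayerGraph` partitions its nodes into named layers (one layer
per node) and allows parallel, undirected, attributed edges between any two
nodes, within or across layers.  Edges carry free-form string attributes with
three reserved keys:

``source``
    the database or file the association came from,
``type``
    ``"direct"`` for an edge read from an input source, ``"transitive"`` for
    an edge synthesised to preserve connectivity when a node was deleted,
``via``
    for transitive edges, the name of the deleted node that induced them.

Deleting a node can optionally derive transitive edges: every unordered pair
of its surviving neighbors that is not already connected (when deduplication
is on) receives one new edge annotated with ``via``.  Deleting a layer deletes
its nodes sequentially with cascading, so a path running through several
deleted nodes still connects its surviving endpoints.

The container is a thin layer over :class:`networkx.MultiGraph`; layer
bookkeeping, transitive derivation and the GraphML/JSON schema live here.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field

import networkx as nx

from .errors import (
    ArgumentError,
    DuplicateLayerError,
    DuplicateNodeError,
    FormatError,
    UnknownEdgeError,
    UnknownLayerError,
    UnknownNodeError,
)

logger = logging.getLogger(__name__)

#: reserved edge-attribute keys
EDGE_TYPE = "type"
EDGE_VIA = "via"
EDGE_SOURCE = "source"


@dataclass(frozen=True)
class Node:
    """A node snapshot: name, owning layer, and its attribute map."""

    name: str
    layer_id: int
    layer_name: str
    attributes: dict = field(default_factory=dict)

    def to_obj(self) -> dict:
        return {
            "name": self.name,
            "layer_id": self.layer_id,
            "layer_name": self.layer_name,
            "attributes": dict(self.attributes),
        }

    @classmethod
    def from_obj(cls, obj: dict) -> "Node":
        return cls(obj["name"], obj["layer_id"], obj["layer_name"], dict(obj["attributes"]))


@dataclass(frozen=True)
class Edge:
    """An edge snapshot: unordered endpoints, multi-edge key, attributes."""

    a: str
    b: str
    key: int
    attributes: dict = field(default_factory=dict)

    @property
    def pair(self) -> tuple:
        return tuple(sorted((self.a, self.b)))

    @property
    def ident(self) -> tuple:
        return self.pair + (self.key,)

    def to_obj(self) -> dict:
        return {"a": self.a, "b": self.b, "key": self.key, "attributes": dict(self.attributes)}

    @classmethod
    def from_obj(cls, obj: dict) -> "Edge":
        return cls(obj["a"], obj["b"], obj["key"], dict(obj["attributes"]))


class MultilayerGraph:
    """Named layers, one layer per node, undirected attributed multi-edges.

    Parameters
    ----------
    name:
        Graph name (may be empty).
    transitive_dedupe:
        When True (default), deleting a node adds a transitive edge between a
        pair of its former neighbors only if no edge currently connects them.
        When False the transitive edge is added as a parallel edge regardless;
        a single deletion still adds at most one edge per neighbor pair.
    """

    def __init__(self, name: str = "", transitive_dedupe: bool = True):
        self.name = name
        self.transitive_dedupe = transitive_dedupe
        self._g = nx.MultiGraph()
        self._layers: dict[int, str] = {}  # id -> name, insertion ordered
        self._next_layer_id = 1

    # ------------------------------------------------------------------ layers
    @property
    def layers(self) -> list:
        """Ordered ``(layer_id, layer_name)`` pairs."""
        return list(self._layers.items())

    def has_layer(self, layer_name: str) -> bool:
        low = layer_name.lower()
        return any(n.lower() == low for n in self._layers.values())

    def layer_id(self, layer_name: str) -> int:
        low = layer_name.lower()
        for lid, n in self._layers.items():
            if n.lower() == low:
                return lid
        raise UnknownLayerError(f"no layer named {layer_name!r}")

    def layer_name(self, layer_id: int) -> str:
        try:
            return self._layers[layer_id]
        except KeyError:
            raise UnknownLayerError(f"no layer with id {layer_id}") from None

    def add_layer(self, layer_name: str) -> int:
        if self.has_layer(layer_name):
            raise DuplicateLayerError(f"layer {layer_name!r} already exists")
        lid = self._next_layer_id
        self._next_layer_id += 1
        self._layers[lid] = layer_name
        return lid

    def _restore_layer(self, layer_id: int, layer_name: str) -> None:
        # used by undo: re-insert a deleted layer under its historical id
        if self.has_layer(layer_name):
            raise DuplicateLayerError(f"layer {layer_name!r} already exists")
        if layer_id in self._layers:
            raise DuplicateLayerError(f"layer id {layer_id} already in use")
        self._layers[layer_id] = layer_name
        self._layers = dict(sorted(self._layers.items()))
        self._next_layer_id = max(self._next_layer_id, layer_id + 1)

    # ------------------------------------------------------------------- nodes
    def has_node(self, name: str) -> bool:
        return name in self._g

    def get_node(self, name: str) -> Node:
        if name not in self._g:
            raise UnknownNodeError(f"no node named {name!r}")
        data = self._g.nodes[name]
        lid = data["layer"]
        attrs = {k: v for k, v in data.items() if k != "layer"}
        return Node(name, lid, self._layers[lid], attrs)

    def nodes(self, layer_name: str | None = None) -> list:
        """All nodes (or those of one layer) in insertion order."""
        if layer_name is None:
            return [self.get_node(n) for n in self._g.nodes]
        lid = self.layer_id(layer_name)
        return [self.get_node(n) for n, d in self._g.nodes(data=True) if d["layer"] == lid]

    def add_node(self, name: str, layer_name: str, attributes: dict | None = None) -> Node:
        if not name:
            raise ArgumentError("node name must be nonempty")
        lid = self.layer_id(layer_name)
        if name in self._g:
            raise DuplicateNodeError(f"node {name!r} already exists")
        self._g.add_node(name, layer=lid, **(attributes or {}))
        return self.get_node(name)

    def update_node_attributes(self, name: str, attributes: dict) -> Node:
        if name not in self._g:
            raise UnknownNodeError(f"no node named {name!r}")
        self._g.nodes[name].update(attributes)
        return self.get_node(name)

    # ------------------------------------------------------------------- edges
    def edges(self) -> list:
        return [Edge(u, v, k, dict(d)) for u, v, k, d in self._g.edges(keys=True, data=True)]

    def edges_between(self, a: str, b: str) -> list:
        if not self._g.has_edge(a, b):
            return []
        return [Edge(a, b, k, dict(d)) for k, d in self._g[a][b].items()]

    def has_edge(self, a: str, b: str) -> bool:
        return self._g.has_edge(a, b)

    def add_edge(self, a: str, b: str, attributes: dict | None = None, *, key: int | None = None) -> Edge:
        for n in (a, b):
            if n not in self._g:
                raise UnknownNodeError(f"no node named {n!r}")
        attrs = dict(attributes or {})
        attrs.setdefault(EDGE_TYPE, "direct")
        if (attrs[EDGE_TYPE] == "transitive") != bool(attrs.get(EDGE_VIA)):
            raise ArgumentError("edge type 'transitive' requires a nonempty 'via' and vice versa")
        if key is None:
            key = self._g.number_of_edges(a, b)
            while self._g.has_edge(a, b, key):
                key += 1
        elif self._g.has_edge(a, b, key):
            raise ArgumentError(f"edge ({a},{b}) key {key} already exists")
        self._g.add_edge(a, b, key=key, **attrs)
        return Edge(a, b, key, attrs)

    def remove_edge(self, a: str, b: str, key="all") -> list:
        """Remove one parallel edge (integer key) or every edge (``"all"``)."""
        if not self._g.has_edge(a, b):
            raise UnknownEdgeError(f"no edge between {a!r} and {b!r}")
        if key == "all":
            removed = self.edges_between(a, b)
            for e in removed:
                self._g.remove_edge(a, b, key=e.key)
            return removed
        if not self._g.has_edge(a, b, key):
            raise UnknownEdgeError(f"no edge ({a!r},{b!r}) with key {key}")
        e = Edge(a, b, key, dict(self._g[a][b][key]))
        self._g.remove_edge(a, b, key=key)
        return [e]

    # ---------------------------------------------------------------- removal
    def remove_node(self, name: str, transitive: bool = False) -> tuple:
        """Remove a node and its incident edges.

        With ``transitive`` on, every unordered pair of distinct former
        neighbors gains one edge ``type="transitive", via=name`` unless an
        edge already connects the pair and ``transitive_dedupe`` is set.
        Self-loops never contribute neighbor pairs.

        Returns ``(removed_edges, added_transitive)``.
        """
        if name not in self._g:
            raise UnknownNodeError(f"no node named {name!r}")
        neighbors = [n for n in self._g.neighbors(name) if n != name]
        removed = [Edge(u, v, k, dict(d)) for u, v, k, d in self._g.edges(name, keys=True, data=True)]
        self._g.remove_node(name)
        added = []
        if transitive:
            for u, w in itertools.combinations(neighbors, 2):
                if self.transitive_dedupe and self._g.has_edge(u, w):
                    continue
                added.append(self.add_edge(u, w, {EDGE_TYPE: "transitive", EDGE_VIA: name}))
        return removed, added

    def remove_layer(self, layer_name: str, transitive: bool = False) -> tuple:
        """Remove a layer: its nodes are removed sequentially in insertion
        order with the given transitive flag, so transitive edges cascade
        through the deleted layer; the layer entry itself is dropped.

        Returns ``(removed_nodes, removed_edges, added_transitive)`` where
        ``removed_edges`` are only edges that existed before the call and
        ``added_transitive`` are the transitive edges still present after it
        (intermediate transitive edges that were consumed by the cascade
        cancel out).
        """
        lid = self.layer_id(layer_name)
        layer_nodes = [n for n, d in self._g.nodes(data=True) if d["layer"] == lid]
        removed_nodes, removed_edges, added_transitive = [], [], []
        pending: dict[tuple, Edge] = {}  # transitive edges added during the cascade
        for n in layer_nodes:
            removed_nodes.append(self.get_node(n))
            rem, add = self.remove_node(n, transitive=transitive)
            for e in rem:
                if e.ident in pending:
                    del pending[e.ident]  # intermediate: added then removed
                else:
                    removed_edges.append(e)
            for e in add:
                pending[e.ident] = e
        added_transitive = list(pending.values())
        del self._layers[lid]
        return removed_nodes, removed_edges, added_transitive

    # ------------------------------------------------------------------- misc
    def copy(self) -> "MultilayerGraph":
        """Independent copy: attribute dicts are copied, not shared."""
        g = MultilayerGraph(self.name, self.transitive_dedupe)
        g._g.add_nodes_from((n, dict(d)) for n, d in self._g.nodes(data=True))
        g._g.add_edges_from(
            (u, v, k, dict(d)) for u, v, k, d in self._g.edges(keys=True, data=True)
        )
        g._layers = dict(self._layers)
        g._next_layer_id = self._next_layer_id
        return g

    def shape(self) -> tuple:
        return (len(self._layers), self._g.number_of_nodes(), self._g.number_of_edges())

    def __repr__(self) -> str:
        l, n, e = self.shape()
        return f"MultilayerGraph({self.name!r}: {l} layers, {n} nodes, {e} edges)"

    # ------------------------------------------------------------ JSON schema
    def to_obj(self) -> dict:
        return {
            "name": self.name,
            "transitive_dedupe": self.transitive_dedupe,
            "next_layer_id": self._next_layer_id,
            "layers": [[lid, name] for lid, name in self._layers.items()],
            "nodes": [n.to_obj() for n in self.nodes()],
            "edges": [e.to_obj() for e in self.edges()],
        }

    @classmethod
    def from_obj(cls, obj: dict) -> "MultilayerGraph":
        try:
            g = cls(obj.get("name", ""), obj.get("transitive_dedupe", True))
            for lid, lname in obj["layers"]:
                g._layers[int(lid)] = lname
            g._next_layer_id = int(obj.get("next_layer_id", max(g._layers, default=0) + 1))
            for n in obj["nodes"]:
                g._g.add_node(n["name"], layer=int(n["layer_id"]), **n["attributes"])
            for e in obj["edges"]:
                g.add_edge(e["a"], e["b"], e["attributes"], key=int(e["key"]))
        except (KeyError, TypeError, ValueError) as exc:
            raise FormatError(f"malformed graph object: {exc}") from exc
        return g


# ---------------------------------------------------------------------- equality
def graphs_equal(g1: MultilayerGraph, g2: MultilayerGraph) -> bool:
    """Structural equality: same layer set, same nodes with equal attributes,
    same edge multiset with equal attributes.  Multi-edge keys are ignored —
    parallel edges are matched as multisets of attribute maps."""
    if set(g1.layers) != set(g2.layers):
        return False
    n1 = {(n.name, n.layer_id, frozenset(n.attributes.items())) for n in g1.nodes()}
    n2 = {(n.name, n.layer_id, frozenset(n.attributes.items())) for n in g2.nodes()}
    if n1 != n2:
        return False
    return _edge_multiset(g1) == _edge_multiset(g2)


def _edge_multiset(g: MultilayerGraph):
    from collections import Counter

    return Counter((e.pair, frozenset(e.attributes.items())) for e in g.edges())


# ------------------------------------------------------------------ file formats
_GRAPHML_EDGE_RENAME = {EDGE_SOURCE: "source_db"}  # avoid shadowing graphml's own vocabulary
_GRAPHML_EDGE_RESTORE = {v: k for k, v in _GRAPHML_EDGE_RENAME.items()}


def export_graph(g: MultilayerGraph, path: str, format: str = "graphml") -> str:
    """Write the graph as GraphML or JSON; returns ``path``.

    The GraphML dialect stores the layer table in a graph-level data key
    ``layers`` (semicolon-joined ``id:name`` pairs), the owning layer name in
    node key ``layer``, and renames the edge attribute ``source`` to
    ``source_db``.
    """
    if format == "json":
        with open(path, "w") as fh:
            json.dump(g.to_obj(), fh, indent=1)
        return path
    if format != "graphml":
        raise ArgumentError(f"unknown format {format!r}")
    out = nx.MultiGraph()
    out.graph["graph_name"] = g.name
    out.graph["transitive_dedupe"] = g.transitive_dedupe
    out.graph["next_layer_id"] = g._next_layer_id
    out.graph["layers"] = ";".join(f"{lid}:{name}" for lid, name in g.layers)
    for n in g.nodes():
        out.add_node(n.name, layer=n.layer_name, **n.attributes)
    for e in g.edges():
        attrs = {_GRAPHML_EDGE_RENAME.get(k, k): v for k, v in e.attributes.items()}
        out.add_edge(e.a, e.b, key=e.key, **attrs)
    nx.write_graphml(out, path)
    return path


def import_graph(path: str, format: str = "graphml") -> MultilayerGraph:
    if format == "json":
        try:
            with open(path) as fh:
                obj = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"not valid JSON: {exc}") from exc
        return MultilayerGraph.from_obj(obj)
    if format != "graphml":
        raise ArgumentError(f"unknown format {format!r}")
    try:
        raw = nx.read_graphml(path, force_multigraph=True)
    except Exception as exc:  # networkx raises several parser error types
        raise FormatError(f"not valid GraphML: {exc}") from exc
    if "layers" not in raw.graph:
        raise FormatError("GraphML file lacks the graph-level 'layers' table")
    g = MultilayerGraph(
        raw.graph.get("graph_name", ""),
        bool(raw.graph.get("transitive_dedupe", True)),
    )
    table = raw.graph["layers"]
    if table:
        for pair in table.split(";"):
            lid, _, lname = pair.partition(":")
            g._layers[int(lid)] = lname
    g._next_layer_id = int(raw.graph.get("next_layer_id", max(g._layers, default=0) + 1))
    for n, d in raw.nodes(data=True):
        attrs = dict(d)
        layer = attrs.pop("layer", None)
        if layer is None:
            raise FormatError(f"node {n!r} lacks the 'layer' key")
        g.add_node(n, layer, attrs)
    for u, v, k, d in raw.edges(keys=True, data=True):
        attrs = {_GRAPHML_EDGE_RESTORE.get(kk, kk): vv for kk, vv in d.items()}
        try:
            key = int(k)
        except (TypeError, ValueError):
            key = None
        try:
            g.add_edge(u, v, attrs, key=key)
        except ArgumentError:
            g.add_edge(u, v, attrs)
    return g


def new_graph(name: str = "", transitive_dedupe: bool = True) -> MultilayerGraph:
    """Create an empty multilayer graph."""
    return MultilayerGraph(name, transitive_dedupe=transitive_dedupe)
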