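"""Pathway to multilayer graph conversion.

One parsed pathway becomes a multilayer graph: each physical entity is a node
placed on the layer named by its class (proteins on ``Protein``, complexes on
``Complex``, RNAs on ``RNA`` and so on, with bare physical entities collected
on the catch-all ``PhysicalEntity`` layer), and interactions become edges.

The edge-derivation convention, since pathway ontologies describe
interactions rather than binary edges, is:

* conversions (biochemical reactions, complex assembly, transport,
  degradation): every left participant connects to every right participant;
* controls (catalysis, modulation, ...): the controller connects to every
  right participant of the controlled conversion (left participants if it has
  no right side; all participants of a controlled non-conversion);
* complex membership: each component connects to its complex;
* participant-only interactions: a clique over the participants.

Every derived edge records the interaction id (``interaction``), the source
file (``source``), and ``type="direct"``.  Interactions never become nodes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .biopax import (
    CONTROL_CLASSES,
    CONVERSION_CLASSES,
    INTERACTION_CLASSES,
    PHYSICAL_ENTITY_CLASSES,
    BiopaxInstance,
    BiopaxModel,
    pathway_components,
)
from .core import MultilayerGraph, new_graph
from .errors import ArgumentError

logger = logging.getLogger(__name__)

#: default class -> layer assignment
DEFAULT_CLASS_TO_LAYER = {
    "Protein": "Protein",
    "Complex": "Complex",
    "Dna": "DNA",
    "DnaRegion": "DNA",
    "Rna": "RNA",
    "RnaRegion": "RNA",
    "SmallMolecule": "SmallMolecule",
    "PhysicalEntity": "PhysicalEntity",
}


@dataclass
class LayerPartitionRule:
    """Maps BioPAX entity classes to layer names; unmapped classes fall back
    to ``default_layer``."""

    class_to_layer: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_TO_LAYER))
    default_layer: str = "PhysicalEntity"


DEFAULT_RULE = LayerPartitionRule()


def classify_instance(instance: BiopaxInstance, rule: LayerPartitionRule = DEFAULT_RULE) -> str:
    """Layer name for a physical-entity instance under the partition rule."""
    if instance.cls in INTERACTION_CLASSES:
        raise ArgumentError(f"{instance.id!r} is an interaction ({instance.cls}), not a physical entity")
    return rule.class_to_layer.get(instance.cls, rule.default_layer)


def _node_names(entities: list) -> dict:
    """entity id -> node name; display names shared by several entities are
    disambiguated by suffixing ``#<id>`` on every collider, so naming does
    not depend on traversal order."""
    counts: dict = {}
    for e in entities:
        if e.display_name:
            counts[e.display_name] = counts.get(e.display_name, 0) + 1
    names = {}
    for e in entities:
        if not e.display_name:
            names[e.id] = e.id
        elif counts[e.display_name] > 1:
            names[e.id] = f"{e.display_name}#{e.id}"
        else:
            names[e.id] = e.display_name
    return names


def pathway_to_multilayer(
    model: BiopaxModel,
    pathway_id: str,
    rule: LayerPartitionRule = DEFAULT_RULE,
    name: str | None = None,
    transitive_dedupe: bool = True,
) -> MultilayerGraph:
    """Build the multilayer graph of one pathway.

    Layers are created lazily in first-touch order, so only populated layers
    exist.  Node attributes record the BioPAX class and id, external
    references and, when present, the cellular location.
    """
    entities, interactions = pathway_components(model, pathway_id)
    g = new_graph(name if name is not None else pathway_id, transitive_dedupe=transitive_dedupe)
    if not entities:
        logger.warning("pathway %r has no physical entities; returning empty graph", pathway_id)
        return g

    names = _node_names(entities)
    for ent in entities:
        layer = classify_instance(ent, rule)
        if not g.has_layer(layer):
            g.add_layer(layer)
        attrs = {"biopax_class": ent.cls, "biopax_id": ent.id}
        if ent.xrefs:
            attrs["xrefs"] = ";".join(f"{db}:{acc}" for db, acc in ent.xrefs)
        loc = _cellular_location(model, ent)
        if loc:
            attrs["cellular_location"] = loc
        g.add_node(names[ent.id], layer, attrs)

    in_graph = set(names)

    def node(eid):
        return names[eid] if eid in in_graph else None

    def add(u, v, interaction_id, extra=None):
        if u is None or v is None or u == v:
            return
        attrs = {"source": model.source_path, "interaction": interaction_id, "type": "direct"}
        if extra:
            attrs.update(extra)
        g.add_edge(u, v, attrs)

    for inter in interactions:
        if inter.cls in CONVERSION_CLASSES or inter.cls == "TemplateReaction":
            lefts = _nodes_of(inter, ("left", "template"), node)
            rights = _nodes_of(inter, ("right", "product"), node)
            for u in lefts:
                for v in rights:
                    add(u, v, inter.id)
        elif inter.cls in CONTROL_CLASSES:
            extra = {}
            ctype = inter.literal("controlType")
            if ctype:
                extra["control_type"] = ctype
            controllers = _nodes_of(inter, ("controller",), node)
            for cid in inter.refs("controlled"):
                target = model.get(cid)
                if target is None:
                    continue
                if target.cls in CONVERSION_CLASSES or target.cls == "TemplateReaction":
                    targets = _nodes_of(target, ("right", "product"), node)
                    if not targets:
                        targets = _nodes_of(target, ("left", "template"), node)
                elif target.cls in INTERACTION_CLASSES:
                    targets = _nodes_of(target, ("participant", "left", "right"), node)
                else:
                    targets = [node(cid)]  # controlled physical entity (rare)
                for u in controllers:
                    for v in targets:
                        add(u, v, inter.id, extra)
        else:  # participant-only interaction classes
            parts = _nodes_of(inter, ("participant",), node)
            for i, u in enumerate(parts):
                for v in parts[i + 1 :]:
                    add(u, v, inter.id)

    # complex membership edges
    for ent in entities:
        if ent.cls != "Complex":
            continue
        cnode = names[ent.id]
        for comp in dict.fromkeys(ent.refs("component")):
            add(node(comp), cnode, ent.id)

    return g


def _nodes_of(inst: BiopaxInstance, props: tuple, node) -> list:
    ids = []
    for p in props:
        ids.extend(inst.refs(p))
    out = []
    for eid in dict.fromkeys(ids):
        n = node(eid)
        if n is not None:
            out.append(n)
    return out


def _cellular_location(model: BiopaxModel, ent: BiopaxInstance) -> str:
    for rid in ent.refs("cellularLocation"):
        voc = model.get(rid)
        if voc is not None:
            term = voc.literal("term")
            if term:
                return term
    return ent.literal("cellularLocation")


def load_rule(path: str) -> LayerPartitionRule:
    """Read a layer-rule override file: ``class: layer`` pairs (YAML/colon
    lines); the key ``default`` overrides the catch-all layer."""
    import yaml

    with open(path) as fh:
        mapping = yaml.safe_load(fh) or {}
    if not isinstance(mapping, dict):
        raise ArgumentError("layer rule file must contain a class: layer mapping")
    default = mapping.pop("default", "PhysicalEntity")
    merged = dict(DEFAULT_CLASS_TO_LAYER)
    merged.update({str(k): str(v) for k, v in mapping.items()})
    return LayerPartitionRule(merged, str(default))
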