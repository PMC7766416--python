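"""Synthetic input generation.

Everything the package reads — BioPAX OWL, DrugBank-dialect XML, the offline
protein TSV — can be generated here as a small, valid, seeded fixture, so the
whole pipeline builds and tests hermetically.  Each generator also returns a
*manifest*: the expected reader/transform outcome (instance counts, node and
edge counts, per-node layer assignment, relation lists, merged-relation
predictions) computed by deliberately naive nested-loop bookkeeping that is
kept independent of the production code paths, so tests can assert against
it as an oracle.

Generation is a pure function of the :class:`FixtureSpec`: the same spec
yields byte-identical files.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from lxml import etree

from .errors import ArgumentError

RDF_NS = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"
OWL_NS = "http://www.w3.org/2002/07/owl#"
BP3_NS = "http://www.biopax.org/release/biopax-level3.owl#"

# naive copy of the default class -> layer assignment, kept separate from the
# transform on purpose (oracle independence)
_NAIVE_LAYER = {
    "Protein": "Protein",
    "Complex": "Complex",
    "Dna": "DNA",
    "Rna": "RNA",
    "SmallMolecule": "SmallMolecule",
    "PhysicalEntity": "PhysicalEntity",
}


@dataclass
class FixtureSpec:
    """Counts and rates controlling one synthetic dataset."""

    seed: int = 0
    # pathway side
    n_proteins: int = 4
    n_complexes: int = 1
    n_rna: int = 1
    n_dna: int = 1
    n_smallmol: int = 1
    n_physical: int = 0  # bare PhysicalEntity instances
    n_reactions: int = 2
    n_controls: int = 1
    n_pathways: int = 1
    include_subpathway: bool = False
    n_dangling: int = 0  # injected dangling references
    collision_rate: float = 0.0  # chance an entity reuses an earlier display name
    # drug / protein side
    n_drugs: int = 3
    n_drug_interactions: int = 1
    n_targets: int = 2
    n_transporters: int = 0
    n_carriers: int = 1
    n_enzymes: int = 1
    n_protein_interactions: int = 2
    n_upkb_xrefs: int = 2
    overlap_rate: float = 0.5  # fraction of TSV drug xrefs copied from DrugBank targets

    def __post_init__(self):
        for name, value in vars(self).items():
            if name.startswith("n_") and value < 0:
                raise ArgumentError(f"{name} must be >= 0, got {value}")

    def rng(self) -> random.Random:
        return random.Random(self.seed)


# --------------------------------------------------------------------- BioPAX
_CLASS_POOLS = (
    ("Protein", "n_proteins", "protein"),
    ("Complex", "n_complexes", "complex"),
    ("Rna", "n_rna", "rna"),
    ("Dna", "n_dna", "dna"),
    ("SmallMolecule", "n_smallmol", "smallmolecule"),
    ("PhysicalEntity", "n_physical", "physentity"),
)


def _plan_pathway(spec: FixtureSpec) -> dict:
    """Random but fully determined pathway structure: entities with classes
    and display names, reactions (left/right), controls, complex components."""
    rng = spec.rng()
    entities = []  # (id, cls, display)
    used_names: dict = {}
    for cls, attr, stem in _CLASS_POOLS:
        for i in range(1, getattr(spec, attr) + 1):
            base = f"{cls} {i}"
            pool = used_names.get(cls, [])
            if pool and rng.random() < spec.collision_rate:
                base = rng.choice(pool)
            used_names.setdefault(cls, []).append(base)
            entities.append((f"{stem}_{i}", cls, base))
    ids = [e[0] for e in entities]

    reactions = []  # (id, left ids, right ids)
    if len(ids) >= 2:
        for i in range(1, spec.n_reactions + 1):
            k_left = min(len(ids) - 1, rng.randint(1, 2))
            left = rng.sample(ids, k_left)
            rest = [x for x in ids if x not in left]
            right = rng.sample(rest, min(len(rest), rng.randint(1, 2)))
            reactions.append((f"reaction_{i}", left, right))

    proteins = [e[0] for e in entities if e[1] == "Protein"]
    controls = []  # (id, controller, reaction id)
    for i in range(1, spec.n_controls + 1):
        if not reactions:
            break
        rid, left, right = reactions[rng.randrange(len(reactions))]
        eligible = [p for p in proteins if p not in left and p not in right]
        if not eligible:
            continue
        controls.append((f"control_{i}", rng.choice(eligible), rid))

    components: dict = {}  # complex id -> component ids
    small = [e[0] for e in entities if e[1] in ("Protein", "SmallMolecule")]
    for eid, cls, _ in entities:
        if cls != "Complex" or not small:
            continue
        pool = [s for s in small if s != eid]
        if pool:
            components[eid] = rng.sample(pool, min(len(pool), rng.randint(1, 2)))

    return {
        "entities": entities,
        "reactions": reactions,
        "controls": controls,
        "components": components,
        "accessions": {
            e[0]: f"P{i:05d}"
            for i, e in enumerate((e for e in entities if e[1] == "Protein"), start=1)
        },
        "rng_tail": rng,
    }


def _naive_node_names(entities) -> dict:
    counts: dict = {}
    for _, _, display in entities:
        counts[display] = counts.get(display, 0) + 1
    return {
        eid: (display if counts[display] == 1 else f"{display}#{eid}")
        for eid, _, display in entities
    }


def _biopax_manifest(spec: FixtureSpec, plan: dict) -> dict:
    entities = plan["entities"]
    names = _naive_node_names(entities)
    node_layers = {names[eid]: _NAIVE_LAYER[cls] for eid, cls, _ in entities}
    layer_counts: dict = {}
    for layer in node_layers.values():
        layer_counts[layer] = layer_counts.get(layer, 0) + 1
    n_edges = 0
    for _, left, right in plan["reactions"]:
        n_edges += len(left) * len(right)
    rx = {rid: (left, right) for rid, left, right in plan["reactions"]}
    for _, _, rid in plan["controls"]:
        left, right = rx[rid]
        n_edges += len(right) if right else len(left)
    for comps in plan["components"].values():
        n_edges += len(comps)
    n_instances = (
        len(entities)
        + len(plan["reactions"])
        + len(plan["controls"])
        + len(plan["accessions"])  # one xref instance per protein
        + spec.n_pathways
        + (1 if spec.include_subpathway else 0)
    )
    return {
        "level": 3,
        "pathway_id": "Pathway1",
        "n_instances": n_instances,
        "n_entities": len(entities),
        "n_interactions": len(plan["reactions"]) + len(plan["controls"]),
        "n_nodes": len(entities),
        "n_edges": n_edges,
        "n_layers": len(layer_counts),
        "layer_counts": layer_counts,
        "node_layers": node_layers,
        "uniprot_accessions": dict(plan["accessions"]),
    }


def gen_biopax(spec: FixtureSpec, path: str) -> tuple:
    """Write a BioPAX Level 3 RDF/XML fixture; returns ``(path, manifest)``.

    The file exercises multiple pathways, sub-pathways, every entity class,
    conversions, controls, complex components, protein UniProt xrefs, name
    collisions and (optionally) dangling references.
    """
    plan = _plan_pathway(spec)
    manifest = _biopax_manifest(spec, plan)

    nsmap = {"rdf": RDF_NS, "bp": BP3_NS, "owl": OWL_NS}
    root = etree.Element(f"{{{RDF_NS}}}RDF", nsmap=nsmap)

    def el(parent, qname, about=None, text=None, resource=None, raw_resource=None):
        ns, local = qname.split(":")
        e = etree.SubElement(parent, f"{{{nsmap[ns]}}}{local}")
        if about is not None:
            e.set(f"{{{RDF_NS}}}about", f"#{about}")
        if resource is not None:
            e.set(f"{{{RDF_NS}}}resource", f"#{resource}")
        if raw_resource is not None:
            e.set(f"{{{RDF_NS}}}resource", raw_resource)
        if text is not None:
            e.text = text
        return e

    onto = el(root, "owl:Ontology")
    onto.set(f"{{{RDF_NS}}}about", "")
    el(onto, "owl:imports", raw_resource="http://www.biopax.org/release/biopax-level3.owl")

    interactions = [rid for rid, _, _ in plan["reactions"]] + [cid for cid, _, _ in plan["controls"]]
    entity_ids = [eid for eid, _, _ in plan["entities"]]
    # the main pathway references every interaction and entity; when a
    # sub-pathway is requested the second half of the interactions moves
    # under it (the closure flattens it back)
    sub_members: list = []
    top_members = interactions
    if spec.include_subpathway and interactions:
        half = len(interactions) // 2
        top_members, sub_members = interactions[:half], interactions[half:]

    pw = el(root, "bp:Pathway", about="Pathway1")
    el(pw, "bp:displayName", text="Fixture pathway 1")
    for rid in top_members:
        el(pw, "bp:pathwayComponent", resource=rid)
    if sub_members:
        el(pw, "bp:pathwayComponent", resource="SubPathway1")
    for eid in entity_ids:
        el(pw, "bp:pathwayComponent", resource=eid)
    for i in range(plan_dangling(spec)):
        el(pw, "bp:pathwayComponent", resource=f"missing_{i + 1}")

    if sub_members:
        sub = el(root, "bp:Pathway", about="SubPathway1")
        el(sub, "bp:displayName", text="Fixture sub-pathway")
        for rid in sub_members:
            el(sub, "bp:pathwayComponent", resource=rid)

    for p in range(2, spec.n_pathways + 1):
        extra = el(root, "bp:Pathway", about=f"Pathway{p}")
        el(extra, "bp:displayName", text=f"Fixture pathway {p}")

    for eid, cls, display in plan["entities"]:
        e = el(root, f"bp:{cls}", about=eid)
        el(e, "bp:displayName", text=display)
        if eid in plan["accessions"]:
            el(e, "bp:xref", resource=f"xref_{eid}")
        for comp in plan["components"].get(eid, []):
            el(e, "bp:component", resource=comp)

    for eid, acc in plan["accessions"].items():
        x = el(root, "bp:UnificationXref", about=f"xref_{eid}")
        el(x, "bp:db", text="UniProtKB")
        el(x, "bp:id", text=acc)

    for rid, left, right in plan["reactions"]:
        r = el(root, "bp:BiochemicalReaction", about=rid)
        for lid in left:
            el(r, "bp:left", resource=lid)
        for rid2 in right:
            el(r, "bp:right", resource=rid2)

    for cid, controller, rid in plan["controls"]:
        c = el(root, "bp:Catalysis", about=cid)
        el(c, "bp:controller", resource=controller)
        el(c, "bp:controlled", resource=rid)
        el(c, "bp:controlType", text="ACTIVATION")

    etree.ElementTree(root).write(
        path, pretty_print=True, xml_declaration=True, encoding="UTF-8"
    )
    return path, manifest


def plan_dangling(spec: FixtureSpec) -> int:
    return spec.n_dangling


# ------------------------------------------------------------------- DrugBank
DB_NS = "http://www.drugbank.ca"


def _plan_drugbank(spec: FixtureSpec) -> dict:
    rng = random.Random(spec.seed + 101)
    drug_ids = [f"DB{i:05d}" for i in range(1, spec.n_drugs + 1)]
    accessions = [f"P{i:05d}" for i in range(1, max(spec.n_proteins, 1) + 1)]

    pairs = [(a, b) for i, a in enumerate(drug_ids) for b in drug_ids[i + 1 :]]
    rng.shuffle(pairs)
    interactions = sorted(pairs[: spec.n_drug_interactions])

    relations = []  # (drug, accession, type)
    for rel_type, count in (
        ("target", spec.n_targets),
        ("transporter", spec.n_transporters),
        ("carrier", spec.n_carriers),
        ("enzyme", spec.n_enzymes),
    ):
        space = [(d, p) for d in drug_ids for p in accessions]
        rng.shuffle(space)
        for d, p in space[:count]:
            relations.append((d, p, rel_type))
    return {"drug_ids": drug_ids, "accessions": accessions, "interactions": interactions, "relations": relations}


def gen_drugbank_xml(spec: FixtureSpec, path: str) -> tuple:
    """Write a DrugBank-dialect XML fixture; returns ``(path, manifest)``.

    Drug–drug interactions are listed under both partners (as the real dump
    does), so the reader's unordered dedupe is exercised.
    """
    plan = _plan_drugbank(spec)
    root = etree.Element(f"{{{DB_NS}}}drugbank", nsmap={None: DB_NS})

    def sub(parent, name, text=None):
        e = etree.SubElement(parent, f"{{{DB_NS}}}{name}")
        if text is not None:
            e.text = text
        return e

    by_drug_rel: dict = {}
    for d, p, t in plan["relations"]:
        by_drug_rel.setdefault(d, []).append((p, t))
    partners: dict = {}
    for a, b in plan["interactions"]:
        partners.setdefault(a, []).append(b)
        partners.setdefault(b, []).append(a)

    for i, did in enumerate(plan["drug_ids"], start=1):
        drug = sub(root, "drug")
        idel = sub(drug, "drugbank-id", did)
        idel.set("primary", "true")
        sub(drug, "drugbank-id", f"APRD{i:05d}")  # secondary id alias
        sub(drug, "name", f"Drug {i}")
        sub(drug, "description", f"Synthetic fixture drug number {i}.")
        inter = sub(drug, "drug-interactions")
        for other in partners.get(did, []):
            di = sub(inter, "drug-interaction")
            sub(di, "drugbank-id", other)
            sub(di, "description", f"{did} with {other}")
        cats = {"target": "targets", "transporter": "transporters", "carrier": "carriers", "enzyme": "enzymes"}
        for t, container in cats.items():
            cont = sub(drug, container)
            for p, rel_t in by_drug_rel.get(did, []):
                if rel_t != t:
                    continue
                rel = sub(cont, t)
                poly = sub(rel, "polypeptide")
                exts = sub(poly, "external-identifiers")
                ext = sub(exts, "external-identifier")
                sub(ext, "resource", "UniProtKB")
                sub(ext, "identifier", p)

    etree.ElementTree(root).write(path, pretty_print=True, xml_declaration=True, encoding="UTF-8")
    manifest = {
        "drug_ids": plan["drug_ids"],
        "n_drugs": len(plan["drug_ids"]),
        "interactions": [list(p) for p in plan["interactions"]],
        "n_interactions": len(plan["interactions"]),
        "relations": [list(r) for r in plan["relations"]],
        "n_relations": len(plan["relations"]),
    }
    return path, manifest


# ---------------------------------------------------------------- protein TSV
def gen_protein_tsv(spec: FixtureSpec, path: str) -> tuple:
    """Write the offline protein table; returns ``(path, manifest)``.

    Cross-consistent with :func:`gen_drugbank_xml` for the same spec: a
    fraction ``overlap_rate`` of the table's DrugBank cross-references copy a
    generated DrugBank *target* relation, so the merged-relation outcome is
    known; the remainder point at drugs outside the generated set.
    """
    db_plan = _plan_drugbank(spec)
    rng = random.Random(spec.seed + 202)
    accessions = db_plan["accessions"]

    pairs = [(a, b) for i, a in enumerate(accessions) for b in accessions[i + 1 :]]
    rng.shuffle(pairs)
    interactions = sorted(pairs[: spec.n_protein_interactions])

    db_targets = [(d, p) for d, p, t in db_plan["relations"] if t == "target"]
    xrefs: dict = {a: [] for a in accessions}
    chosen = set()
    for i in range(spec.n_upkb_xrefs):
        if db_targets and rng.random() < spec.overlap_rate:
            d, p = db_targets[rng.randrange(len(db_targets))]
        else:
            d, p = f"DB9{rng.randint(1000, 9999)}", rng.choice(accessions)
        if (d, p) in chosen:
            continue
        chosen.add((d, p))
        xrefs[p].append(d)

    partners: dict = {a: [] for a in accessions}
    for a, b in interactions:
        partners[a].append(b)
        partners[b].append(a)

    lines = ["accession\tname\tgene\torganism\tinteractions\tdrugbank"]
    for i, acc in enumerate(accessions, start=1):
        lines.append(
            "\t".join(
                [
                    acc,
                    f"Fixture protein {i}",
                    f"GEN{i}",
                    "Homo sapiens",
                    ";".join(partners[acc]),
                    ";".join(xrefs[acc]),
                ]
            )
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")

    # naive merged-relation prediction for protein_ids=accessions and
    # drug_ids=the generated drug set
    drug_set = set(db_plan["drug_ids"])
    merged: dict = {}
    for p, ds in xrefs.items():
        for d in ds:
            if d in drug_set:
                merged[(d, p, "target")] = {"UniProt"}
    for d, p, t in db_plan["relations"]:
        key = (d, p, t)
        merged.setdefault(key, set()).add("DrugBank")
    manifest = {
        "accessions": accessions,
        "n_records": len(accessions),
        "interactions": [list(p) for p in interactions],
        "drugbank_xrefs": xrefs,
        "merged_relations": sorted(
            [d, p, t, sorted(srcs)] for (d, p, t), srcs in merged.items()
        ),
    }
    return path, manifest


# ------------------------------------------------------------- op sequences
def gen_random_ops(g, n: int, seed: int) -> list:
    """A seeded sequence of ``n`` valid ``add_step`` argument tuples
    ``(action, element, name, extra)`` for a graph starting from ``g``.

    Each tuple is valid at its position; validity is maintained by advancing
    a scratch view alongside the generation.
    """
    from .views import add_step, create_view

    if n < 0:
        raise ArgumentError(f"n must be >= 0, got {n}")
    rng = random.Random(seed)
    scratch = create_view(g)
    ops = []
    counter = {"layer": 0, "node": 0, "edge": 0}
    for _ in range(n):
        cur = scratch.current
        choices = ["add_layer"]
        layer_names = [name for _, name in cur.layers]
        node_names = [nd.name for nd in cur.nodes()]
        edges = cur.edges()
        if layer_names:
            choices += ["add_node", "remove_layer"]
        if node_names:
            choices += ["add_edge", "remove_node"]
        if edges:
            choices += ["remove_edge", "remove_edge"]
        kind = rng.choice(choices)
        if kind == "add_layer":
            counter["layer"] += 1
            op = ("add", "layer", f"L{counter['layer']}", {})
        elif kind == "add_node":
            counter["node"] += 1
            op = (
                "add",
                "node",
                f"N{counter['node']}",
                {"layer": rng.choice(layer_names), "attributes": {"tag": str(counter["node"])}},
            )
        elif kind == "add_edge":
            a = rng.choice(node_names)
            b = rng.choice(node_names)
            counter["edge"] += 1
            op = ("add", "edge", f"{a}--{b}", {"a": a, "b": b, "attributes": {"source": "ops"}})
        elif kind == "remove_node":
            name = rng.choice(node_names)
            op = ("remove", "node", name, {"transitive": rng.random() < 0.5})
        elif kind == "remove_layer":
            name = rng.choice(layer_names)
            op = ("remove", "layer", name, {"transitive": rng.random() < 0.5})
        else:  # remove_edge
            e = edges[rng.randrange(len(edges))]
            key = e.key if rng.random() < 0.5 else "all"
            op = ("remove", "edge", f"{e.a}--{e.b}", {"a": e.a, "b": e.b, "key": key})
        add_step(scratch, *op[:3], op[3])
        ops.append(op)
    return ops


def gen_random_graph(seed: int, max_nodes: int = 40) -> "MultilayerGraph":
    """A seeded random multilayer multigraph (layers, nodes, parallel edges,
    self-loops) for property tests."""
    from .core import new_graph

    rng = random.Random(seed)
    g = new_graph(f"rand{seed}")
    n_layers = rng.randint(1, 4)
    for i in range(1, n_layers + 1):
        g.add_layer(f"Layer{i}")
    layer_names = [name for _, name in g.layers]
    n_nodes = rng.randint(0, max_nodes)
    for i in range(1, n_nodes + 1):
        g.add_node(f"n{i}", rng.choice(layer_names), {"idx": str(i)})
    nodes = [nd.name for nd in g.nodes()]
    if nodes:
        n_edges = rng.randint(0, 2 * len(nodes))
        for _ in range(n_edges):
            a, b = rng.choice(nodes), rng.choice(nodes)
            g.add_edge(a, b, {"source": f"s{rng.randint(1, 3)}"})
    return g
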