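"""BioPAX Level 2/3 OWL (RDF/XML) reader.

Reads a pathway-knowledge file into a flat instance table: every OWL
individual of a BioPAX class becomes a :class:`BiopaxInstance` holding its
class, display name, property multimap and external-reference list.  The
reader is deliberately shallow — it interprets only ``rdf:resource``-style
references and literal properties, in document order, and performs no OWL
reasoning.  Level 2 class and property names are canonicalised to their
Level 3 spelling at read time so everything downstream is level-agnostic.

Dangling references (common in public exports) are skipped with a logged
warning rather than treated as fatal.
"""

from __future__ import annotations

import logging
import os
import urllib.request
from dataclasses import dataclass, field

from lxml import etree

from .errors import (
    ArgumentError,
    FormatError,
    InputError,
    NetworkDisabledError,
    UnknownPathwayError,
    UnsupportedLevelError,
)

logger = logging.getLogger(__name__)

RDF_NS = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"
OWL_NS = "http://www.w3.org/2002/07/owl#"
BP3_NS = "http://www.biopax.org/release/biopax-level3.owl#"
BP2_NS = "http://www.biopax.org/release/biopax-level2.owl#"

# Level 3 class vocabulary (subset relevant to graph building; anything else
# found in the biopax namespace is kept and flagged foreign).
PHYSICAL_ENTITY_CLASSES = {
    "PhysicalEntity",
    "Protein",
    "Dna",
    "DnaRegion",
    "Rna",
    "RnaRegion",
    "SmallMolecule",
    "Complex",
    "Gene",
}
INTERACTION_CLASSES = {
    "Interaction",
    "MolecularInteraction",
    "GeneticInteraction",
    "Conversion",
    "BiochemicalReaction",
    "ComplexAssembly",
    "Transport",
    "TransportWithBiochemicalReaction",
    "Degradation",
    "Control",
    "Catalysis",
    "Modulation",
    "TemplateReaction",
    "TemplateReactionRegulation",
}
CONVERSION_CLASSES = {
    "Conversion",
    "BiochemicalReaction",
    "ComplexAssembly",
    "Transport",
    "TransportWithBiochemicalReaction",
    "Degradation",
}
CONTROL_CLASSES = {"Control", "Catalysis", "Modulation", "TemplateReactionRegulation"}
UTILITY_CLASSES = {
    "UnificationXref",
    "RelationshipXref",
    "PublicationXref",
    "Xref",
    "BioSource",
    "Provenance",
    "Stoichiometry",
    "CellularLocationVocabulary",
    "ControlledVocabulary",
    "SequenceSite",
    "SequenceInterval",
    "Evidence",
    "Score",
}
KNOWN_CLASSES = PHYSICAL_ENTITY_CLASSES | INTERACTION_CLASSES | UTILITY_CLASSES | {"Pathway"}
XREF_CLASSES = {"UnificationXref", "RelationshipXref", "PublicationXref", "Xref"}

# Level 2 -> Level 3 canonicalisation
_L2_CLASSES = {
    "pathway": "Pathway",
    "protein": "Protein",
    "dna": "Dna",
    "rna": "Rna",
    "smallMolecule": "SmallMolecule",
    "complex": "Complex",
    "physicalEntity": "PhysicalEntity",
    "biochemicalReaction": "BiochemicalReaction",
    "complexAssembly": "ComplexAssembly",
    "transport": "Transport",
    "transportWithBiochemicalReaction": "TransportWithBiochemicalReaction",
    "control": "Control",
    "catalysis": "Catalysis",
    "modulation": "Modulation",
    "interaction": "Interaction",
    "physicalInteraction": "MolecularInteraction",
    "unificationXref": "UnificationXref",
    "relationshipXref": "RelationshipXref",
    "publicationXref": "PublicationXref",
    "bioSource": "BioSource",
}
_L2_PROPS = {
    "NAME": "displayName",
    "SHORT-NAME": "displayName",
    "LEFT": "left",
    "RIGHT": "right",
    "CONTROLLER": "controller",
    "CONTROLLED": "controlled",
    "COMPONENTS": "component",
    "PARTICIPANTS": "participant",
    "PATHWAY-COMPONENTS": "pathwayComponent",
    "XREF": "xref",
    "DB": "db",
    "ID": "id",
    "CONTROL-TYPE": "controlType",
}

#: properties followed when resolving pathway membership
_REF_PROPS = (
    "pathwayComponent",
    "left",
    "right",
    "controller",
    "controlled",
    "component",
    "participant",
    "product",
    "template",
    "memberPhysicalEntity",
)


@dataclass(frozen=True)
class Ref:
    """A reference to another instance (by normalised local id)."""

    id: str


@dataclass
class BiopaxInstance:
    """One OWL individual: id, class, display name, properties, xrefs."""

    id: str
    cls: str
    display_name: str = ""
    properties: dict = field(default_factory=dict)  # name -> list[str | Ref]
    xrefs: list = field(default_factory=list)  # [(db, accession)] in file order
    foreign: bool = False

    def refs(self, prop: str) -> list:
        return [v.id for v in self.properties.get(prop, []) if isinstance(v, Ref)]

    def literal(self, prop: str) -> str:
        for v in self.properties.get(prop, []):
            if not isinstance(v, Ref):
                return v
        return ""


@dataclass
class BiopaxModel:
    """All instances parsed from one OWL file."""

    level: int
    instances: list
    source_path: str

    def __post_init__(self):
        self.by_id = {}
        for inst in self.instances:
            if inst.id in self.by_id:
                raise FormatError(f"duplicate instance id {inst.id!r}")
            self.by_id[inst.id] = inst

    def get(self, instance_id: str) -> BiopaxInstance | None:
        return self.by_id.get(instance_id)


def _localname(tag: str) -> tuple:
    ns, _, local = tag.rpartition("}")
    return ns.lstrip("{"), local


def _normalize_id(uri: str) -> str:
    if "#" in uri:
        return uri.rsplit("#", 1)[1]
    return uri.rstrip("/").rsplit("/", 1)[-1]


def _detect_level(root) -> int:
    # rdf:type namespaces take precedence; fall back to declared namespaces
    # and owl:imports so an instance-free header still identifies its level.
    for el in root.iter(etree.Element):
        ns, _ = _localname(el.tag)
        if ns == BP3_NS:
            return 3
        if ns == BP2_NS:
            return 2
    declared = " ".join(str(v) for v in (root.nsmap or {}).values())
    for el in root.iter(f"{{{OWL_NS}}}Ontology"):
        for imp in el.iter(f"{{{OWL_NS}}}imports"):
            declared += " " + (imp.get(f"{{{RDF_NS}}}resource") or "")
    if "biopax-level3" in declared:
        return 3
    if "biopax-level2" in declared:
        return 2
    raise UnsupportedLevelError("file is neither BioPAX Level 2 nor Level 3")


def read_biopax(path: str) -> BiopaxModel:
    """Parse a BioPAX OWL file into a :class:`BiopaxModel`.

    Raises :class:`InputError` if the file is missing, :class:`FormatError`
    if it is not well-formed XML, and :class:`UnsupportedLevelError` if no
    BioPAX Level 2/3 namespace is present.
    """
    if not os.path.exists(path):
        raise InputError(f"no such file: {path}")
    try:
        tree = etree.parse(path)
    except etree.XMLSyntaxError as exc:
        raise FormatError(f"not parseable as XML: {exc}") from exc
    root = tree.getroot()
    level = _detect_level(root)
    bp_ns = BP3_NS if level == 3 else BP2_NS

    instances = []
    for el in root.iter(etree.Element):
        ns, cls = _localname(el.tag)
        if ns != bp_ns:
            continue
        about = el.get(f"{{{RDF_NS}}}about")
        rdf_id = el.get(f"{{{RDF_NS}}}ID")
        if about is None and rdf_id is None:
            continue  # a property element, not an individual
        iid = _normalize_id(about) if about is not None else rdf_id
        if level == 2:
            cls = _L2_CLASSES.get(cls, cls)
        foreign = cls not in KNOWN_CLASSES
        if foreign:
            logger.warning("unknown BioPAX class %r for instance %r (kept, flagged foreign)", cls, iid)
        props: dict = {}
        for child in el:
            if not isinstance(child.tag, str):
                continue
            _, pname = _localname(child.tag)
            if level == 2:
                pname = _L2_PROPS.get(pname, pname)
            resource = child.get(f"{{{RDF_NS}}}resource")
            if resource is not None:
                value: object = Ref(_normalize_id(resource))
            elif child.text is not None and child.text.strip():
                value = child.text.strip()
            else:
                continue
            props.setdefault(pname, []).append(value)
        display = ""
        for name_prop in ("displayName", "name", "standardName"):
            lit = next((v for v in props.get(name_prop, []) if not isinstance(v, Ref)), "")
            if lit:
                display = lit
                break
        instances.append(BiopaxInstance(iid, cls, display, props, [], foreign))

    model = BiopaxModel(level, instances, path)
    _resolve_xrefs(model)
    return model


def _resolve_xrefs(model: BiopaxModel) -> None:
    for inst in model.instances:
        for xid in inst.refs("xref"):
            target = model.get(xid)
            if target is None:
                logger.warning("dangling xref %r on %r", xid, inst.id)
                continue
            if target.cls in XREF_CLASSES:
                db, acc = target.literal("db"), target.literal("id")
                if db or acc:
                    inst.xrefs.append((db, acc))


def list_pathways(model: BiopaxModel) -> list:
    """All pathway instances as ``(pathway_id, display_name)``, in file order."""
    return [(i.id, i.display_name) for i in model.instances if i.cls == "Pathway"]


def pathway_components(model: BiopaxModel, pathway_id: str) -> tuple:
    """Transitive closure of one pathway's membership references.

    Follows ``pathwayComponent`` plus interaction participants (left, right,
    controller, controlled, component, participant, ...) breadth-first.
    Sub-pathways are flattened: their components are included but the
    sub-pathway itself becomes neither entity nor interaction.

    Returns ``(entities, interactions)`` — physical-entity instances and
    interaction instances, each listed once in first-encounter order.
    """
    start = model.get(pathway_id)
    if start is None or start.cls != "Pathway":
        raise UnknownPathwayError(f"{pathway_id!r} does not name a Pathway instance")
    entities: list = []
    interactions: list = []
    visited = {pathway_id}
    queue = list(dict.fromkeys(_member_refs(start)))
    while queue:
        rid = queue.pop(0)
        if rid in visited:
            continue
        visited.add(rid)
        inst = model.get(rid)
        if inst is None:
            logger.warning("dangling reference %r in pathway %r (skipped)", rid, pathway_id)
            continue
        if inst.cls == "Pathway":
            queue.extend(_member_refs(inst))
            continue
        if inst.cls in INTERACTION_CLASSES:
            interactions.append(inst)
            queue.extend(_member_refs(inst))
        elif inst.cls in PHYSICAL_ENTITY_CLASSES:
            entities.append(inst)
            queue.extend(_member_refs(inst))
        # utility classes (xrefs, vocabularies, ...) are not members
    return entities, interactions


def _member_refs(inst: BiopaxInstance) -> list:
    out = []
    for prop in _REF_PROPS:
        out.extend(inst.refs(prop))
    return out


def get_external_ids(model: BiopaxModel, instance_ids: list, database: str) -> dict:
    """Map each requested instance id to its accessions in ``database``.

    The database name is matched case-insensitively as a substring, so
    ``"UniProt"`` matches ``"UniProtKB"`` and ``"UniProt Knowledgebase"``.
    Unknown ids map to an empty list with a warning.
    """
    needle = database.lower()
    out: dict = {}
    for iid in instance_ids:
        inst = model.get(iid)
        if inst is None:
            logger.warning("unknown instance id %r", iid)
            out[iid] = []
            continue
        out[iid] = [acc for db, acc in inst.xrefs if needle in db.lower()]
    return out


_REACTOME_URL = "https://reactome.org/ReactomeRESTfulAPI/RESTfulWS/biopaxExporter/Level{level}/{acc}"


def download_pathway(pathway_accession: str, level: int, dest: str, *, allow_network: bool = False) -> str:
    """Fetch one pathway from Reactome as BioPAX Level 2 or 3 OWL.

    Network access is off by default; pass ``allow_network=True`` to opt in.
    Never used by the test suite.
    """
    if level not in (2, 3):
        raise ArgumentError(f"level must be 2 or 3, got {level}")
    if not allow_network:
        raise NetworkDisabledError(
            "network access is disabled by default; pass allow_network=True "
            "(CLI: --allow-network) or download the OWL file manually"
        )
    url = _REACTOME_URL.format(level=level, acc=pathway_accession)
    try:
        with urllib.request.urlopen(url) as resp, open(dest, "wb") as fh:
            fh.write(resp.read())
    except Exception as exc:
        raise InputError(f"download failed: {exc}") from exc
    return dest
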