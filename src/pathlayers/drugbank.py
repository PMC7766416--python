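"""DrugBank-format XML integration.

DrugBank distributes its full database as one large XML file (download
requires a license, so this module never fetches anything — the caller
supplies a local path).  The reader extracts drugs, pairwise drug–drug
interactions, and the four drug→protein relation classes (targets,
transporters, carriers, enzymes) via each relation's polypeptide UniProtKB
external identifier.  Parsing happens once; the returned
:class:`DrugBankData` is reused by every drug-related function.

A Drug layer is added to a multilayer graph in two stages, mirroring the
integration workflow: the layer with drug nodes and drug–drug interaction
edges first, then the drug↔protein connections from the merged relation list
(see :mod:`pathlayers.uniprot`).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

from lxml import etree

from .core import MultilayerGraph
from .errors import ArgumentError, FormatError

logger = logging.getLogger(__name__)

#: the four drug→protein association classes, in reporting order
RELATION_TYPES = ("target", "transporter", "carrier", "enzyme")


@dataclass(frozen=True)
class DrugProteinRelation:
    """A drug↔protein association with its type and originating database(s)."""

    drugbank_id: str
    uniprot_id: str
    relation_type: str
    sources: frozenset = frozenset({"DrugBank"})

    def __post_init__(self):
        if self.relation_type not in RELATION_TYPES:
            raise ArgumentError(
                f"relation_type must be one of {RELATION_TYPES}, got {self.relation_type!r}"
            )

    @property
    def key(self) -> tuple:
        return (self.drugbank_id, self.uniprot_id, self.relation_type)

_PRIMARY_ID_RE = re.compile(r"^DB\d{5}$")
_CATEGORY_TAGS = {
    "targets": "target",
    "transporters": "transporter",
    "carriers": "carrier",
    "enzymes": "enzyme",
}


@dataclass
class DrugRecord:
    """One drug entry: primary DrugBank id, name, free-form attributes."""

    drugbank_id: str
    name: str
    attributes: dict = field(default_factory=dict)


@dataclass
class DrugBankData:
    """Parsed content of one DrugBank XML file."""

    drugs: dict = field(default_factory=dict)  # primary id -> DrugRecord
    drug_drug: list = field(default_factory=list)  # [(id_a, id_b, description)]
    relations: list = field(default_factory=list)  # [DrugProteinRelation]
    aliases: dict = field(default_factory=dict)  # secondary id -> primary id

    def resolve(self, drug_id: str) -> str | None:
        if drug_id in self.drugs:
            return drug_id
        return self.aliases.get(drug_id)


def _local(el) -> str:
    return etree.QName(el).localname if isinstance(el.tag, str) else ""


def _child_text(el, name: str) -> str:
    for c in el:
        if _local(c) == name and c.text:
            return c.text.strip()
    return ""


def load_db_xml(path: str) -> DrugBankData:
    """Parse a DrugBank-dialect XML file.

    Raises :class:`FormatError` for malformed XML or a root element other
    than ``drugbank``.  Relations whose polypeptide carries no UniProtKB
    identifier are skipped with a warning.
    """
    try:
        tree = etree.parse(path)
    except etree.XMLSyntaxError as exc:
        raise FormatError(f"not parseable as XML: {exc}") from exc
    root = tree.getroot()
    if _local(root) != "drugbank":
        raise FormatError(f"root element is {_local(root)!r}, expected 'drugbank'")

    data = DrugBankData()
    raw_pairs: list = []
    for drug in root:
        if _local(drug) != "drug":
            continue
        primary, secondaries = "", []
        for c in drug:
            if _local(c) == "drugbank-id" and c.text:
                txt = c.text.strip()
                if c.get("primary") == "true" and not primary:
                    primary = txt
                else:
                    secondaries.append(txt)
        if not primary:  # no primary flag: first DBxxxxx-shaped id wins
            for txt in list(secondaries):
                if _PRIMARY_ID_RE.match(txt):
                    primary = txt
                    secondaries.remove(txt)
                    break
        if not primary:
            logger.warning("drug entry with no usable id skipped")
            continue
        attrs = {}
        for key in ("description", "groups", "indication"):
            if key == "groups":
                groups = [
                    _child_text(gc, "") or (gc.text or "").strip()
                    for c in drug
                    if _local(c) == "groups"
                    for gc in c
                    if _local(gc) == "group"
                ]
                if groups:
                    attrs["groups"] = ";".join(g for g in groups if g)
                continue
            val = _child_text(drug, key)
            if val:
                attrs[key] = val
        data.drugs[primary] = DrugRecord(primary, _child_text(drug, "name"), attrs)
        for sec in secondaries:
            data.aliases[sec] = primary

        for c in drug:
            tag = _local(c)
            if tag == "drug-interactions":
                for di in c:
                    if _local(di) != "drug-interaction":
                        continue
                    other = _child_text(di, "drugbank-id")
                    if other:
                        raw_pairs.append((primary, other, _child_text(di, "description")))
            elif tag in _CATEGORY_TAGS:
                rel_type = _CATEGORY_TAGS[tag]
                for rel in c:
                    if _local(rel) != rel_type:
                        continue
                    acc = _polypeptide_uniprot(rel)
                    if not acc:
                        logger.warning(
                            "%s of %s has no polypeptide UniProtKB id; skipped", rel_type, primary
                        )
                        continue
                    data.relations.append(
                        DrugProteinRelation(primary, acc, rel_type, frozenset({"DrugBank"}))
                    )

    # drug-drug interactions are listed under each partner: dedupe on the
    # unordered pair, keeping the first description seen
    seen = set()
    for a, b, desc in raw_pairs:
        pair = tuple(sorted((a, b)))
        if pair in seen:
            continue
        seen.add(pair)
        data.drug_drug.append((a, b, desc))

    for rel in data.relations:
        if rel.drugbank_id not in data.drugs:
            logger.warning("relation references unknown drug %s (kept)", rel.drugbank_id)
    return data


def _polypeptide_uniprot(rel_el) -> str:
    for poly in rel_el:
        if _local(poly) != "polypeptide":
            continue
        for ext in poly.iter():
            if _local(ext) == "external-identifier":
                res = _child_text(ext, "resource")
                if "uniprot" in res.lower():
                    return _child_text(ext, "identifier")
    return ""


def get_db_drug(db: DrugBankData, ids: list) -> tuple:
    """Fetch drug records in request order.

    Returns ``(records, unknown_ids)``; unknown ids are also logged.
    """
    records, unknown = [], []
    for i in ids:
        primary = db.resolve(i)
        if primary is None:
            unknown.append(i)
            logger.warning("unknown DrugBank id %r", i)
        else:
            records.append(db.drugs[primary])
    return records, unknown


def get_db_interactions(db: DrugBankData, ids: list) -> list:
    """Drug–drug interactions with BOTH endpoints among ``ids``; unordered
    pairs, deduplicated."""
    wanted = {db.resolve(i) for i in ids} - {None}
    out = []
    for a, b, desc in db.drug_drug:
        if a in wanted and b in wanted:
            out.append((a, b, {"description": desc} if desc else {}))
    return out


def _relations_of_type(db: DrugBankData, drug_ids: list, relation_type: str) -> list:
    wanted = {db.resolve(i) for i in drug_ids} - {None}
    return [r for r in db.relations if r.relation_type == relation_type and r.drugbank_id in wanted]


def get_db_targets(db, drug_ids):
    """Drug→protein *target* relations (pharmacological action sites)."""
    return _relations_of_type(db, drug_ids, "target")


def get_db_transporters(db, drug_ids):
    """Drug→protein *transporter* relations."""
    return _relations_of_type(db, drug_ids, "transporter")


def get_db_carriers(db, drug_ids):
    """Drug→protein *carrier* relations."""
    return _relations_of_type(db, drug_ids, "carrier")


def get_db_enzymes(db, drug_ids):
    """Drug→protein *enzyme* (metabolizing) relations."""
    return _relations_of_type(db, drug_ids, "enzyme")


def get_db_to_upkb(db: DrugBankData, drug_ids: list, relation_types="all") -> list:
    """Union of the four drug→protein relation classes for the given drugs.

    ``relation_types`` is ``"all"`` or a subset of
    ``{"target", "transporter", "carrier", "enzyme"}``.
    """
    if relation_types == "all":
        types = list(RELATION_TYPES)
    else:
        types = list(relation_types)
        bad = [t for t in types if t not in RELATION_TYPES]
        if bad:
            raise ArgumentError(f"invalid relation type(s) {bad}; expected subset of {sorted(RELATION_TYPES)}")
    out = []
    for t in RELATION_TYPES:  # stable order
        if t in types:
            out.extend(_relations_of_type(db, drug_ids, t))
    return out


def add_drug_layer(
    g: MultilayerGraph, db: DrugBankData, drug_ids: list, layer_name: str = "Drug"
) -> MultilayerGraph:
    """Add a Drug layer: one node per resolvable drug id and the drug–drug
    interaction edges among them (``source="DrugBank"``).  Drug→protein
    edges are added separately via the merged relation list."""
    g.add_layer(layer_name)  # raises DuplicateLayerError if taken
    resolved = []
    for i in drug_ids:
        primary = db.resolve(i)
        if primary is None:
            logger.warning("drug id %r not in the parsed data; node skipped", i)
            continue
        if primary in resolved:
            continue
        resolved.append(primary)
        rec = db.drugs[primary]
        attrs = {"name": rec.name, "node_type": "drug"}
        g.add_node(primary, layer_name, attrs)
    for a, b, attrs in get_db_interactions(db, resolved):
        g.add_edge(a, b, {**attrs, "source": "DrugBank", "type": "direct"})
    return g
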