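"""Protein records, protein–protein interactions and protein→drug
cross-references.

The default source is *offline*: a TSV with one row per UniProtKB accession
and semicolon-separated ``interactions`` / ``drugbank`` list columns.  An
*online* source wraps an injectable transport callable and chunks queries
into batches of at most 50 accessions, the limit the UniProt web service
recommends per query; both modes answer through the same interface, so the
rest of the package is source-agnostic.

The module also owns the cross-database merge: drug–protein relations found
in both DrugBank and the protein source are unified on
``(drug, protein, relation_type)`` with their source sets unioned, so every
edge knows which database(s) assert it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .core import MultilayerGraph
from .drugbank import DrugBankData, DrugProteinRelation, get_db_to_upkb
from .errors import ArgumentError, FormatError

logger = logging.getLogger(__name__)

#: UniProt's recommended maximum ids per query
MAX_BATCH = 50
_LIST_COLUMNS = ("interactions", "drugbank")


@dataclass
class ProteinRecord:
    """One protein: accession, attribute columns, partner and drug lists."""

    uniprot_id: str
    attributes: dict = field(default_factory=dict)
    interactions: list = field(default_factory=list)
    drugbank_xrefs: list = field(default_factory=list)


class ProteinSource:
    """Common interface of offline/online protein sources."""

    mode = "offline"

    def fetch(self, ids: list) -> dict:  # accession -> ProteinRecord | None
        raise NotImplementedError

    def columns(self) -> list:
        raise NotImplementedError


class OfflineProteinSource(ProteinSource):
    """In-memory table of protein records (the hermetic default)."""

    mode = "offline"

    def __init__(self, records: dict):
        self.records = records

    def fetch(self, ids: list) -> dict:
        return {i: self.records.get(i) for i in ids}

    def columns(self) -> list:
        cols: list = []
        for rec in self.records.values():
            for c in rec.attributes:
                if c not in cols:
                    cols.append(c)
        return cols


class OnlineProteinSource(ProteinSource):
    """Batched adapter over an injectable transport.

    ``transport(ids)`` must return ``{accession: ProteinRecord}`` for one
    batch; this class only splits requests into chunks of ``batch_size``
    (capped at 50) and concatenates the answers.
    """

    mode = "online"

    def __init__(self, transport, batch_size: int = MAX_BATCH):
        if not 1 <= batch_size <= MAX_BATCH:
            raise ArgumentError(f"batch_size must be in [1, {MAX_BATCH}], got {batch_size}")
        self.transport = transport
        self.batch_size = batch_size

    def fetch(self, ids: list) -> dict:
        out: dict = {}
        for i in range(0, len(ids), self.batch_size):
            out.update(self.transport(list(ids[i : i + self.batch_size])))
        return {i: out.get(i) for i in ids}

    def columns(self) -> list:
        return []


def load_protein_table(path: str) -> OfflineProteinSource:
    """Read the offline TSV: an ``accession`` column plus one column per
    attribute; ``interactions`` and ``drugbank`` hold semicolon-joined lists.
    Duplicate accessions are an error."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"not a readable TSV: {exc}") from exc
    if "accession" not in df.columns:
        raise FormatError("protein table lacks the 'accession' column")
    records: dict = {}
    for _, row in df.iterrows():
        acc = row["accession"].strip()
        if not acc:
            raise FormatError("empty accession in protein table")
        if acc in records:
            raise FormatError(f"duplicate accession {acc!r} in protein table")
        attrs = {
            c: row[c] for c in df.columns if c not in ("accession",) + _LIST_COLUMNS
        }
        records[acc] = ProteinRecord(
            acc,
            attrs,
            _split_list(row.get("interactions", "")),
            _split_list(row.get("drugbank", "")),
        )
    return OfflineProteinSource(records)


def _split_list(cell: str) -> list:
    return [x.strip() for x in str(cell).split(";") if x.strip()]


# ----------------------------------------------------------------------- queries
def get_up_info(src: ProteinSource, ids: list, columns: list) -> pd.DataFrame:
    """Attribute table for the requested accessions, one row per id in
    request order.  Unknown ids yield empty cells with a warning; unknown
    columns (offline mode) are an error."""
    if src.mode == "offline":
        known = src.columns()
        bad = [c for c in columns if c not in known]
        if bad:
            raise ArgumentError(f"unknown column(s) {bad}; available: {known}")
    fetched = src.fetch(list(ids))
    rows = []
    for i in ids:
        rec = fetched.get(i)
        if rec is None:
            logger.warning("unknown protein accession %r", i)
            rows.append({"accession": i, **{c: "" for c in columns}})
        else:
            rows.append({"accession": i, **{c: rec.attributes.get(c, "") for c in columns}})
    return pd.DataFrame(rows, columns=["accession", *columns])


def get_up_interactions(src: ProteinSource, ids: list) -> list:
    """Protein–protein interaction pairs with both endpoints among ``ids``;
    symmetric listings are deduplicated to one unordered pair."""
    wanted = set(ids)
    fetched = src.fetch(list(ids))
    seen, out = set(), []
    for i in ids:
        rec = fetched.get(i)
        if rec is None:
            continue
        for partner in rec.interactions:
            if partner not in wanted or partner == i:
                continue
            pair = tuple(sorted((i, partner)))
            if pair not in seen:
                seen.add(pair)
                out.append(pair)
    return out


def get_upkb_to_db(src: ProteinSource, ids: list) -> list:
    """Protein→drug relations from the source's DrugBank cross-references;
    every xref becomes a ``target`` relation attributed to UniProt."""
    fetched = src.fetch(list(ids))
    out, seen = [], set()
    for i in ids:
        rec = fetched.get(i)
        if rec is None:
            continue
        for db_id in rec.drugbank_xrefs:
            key = (db_id, i)
            if key in seen:
                continue
            seen.add(key)
            out.append(DrugProteinRelation(db_id, i, "target", frozenset({"UniProt"})))
    return out


# ------------------------------------------------------------------------ layers
def add_protein_layer(
    g: MultilayerGraph,
    src: ProteinSource,
    ids: list,
    columns: list | None = None,
    layer_name: str = "Protein",
) -> MultilayerGraph:
    """Add (or extend) a Protein layer: one node per accession with the
    requested attribute columns, plus interaction edges among the ids
    (``source="UniProt"``).  Accessions already present as nodes keep their
    node and get their attributes merged."""
    columns = list(columns or [])
    if not g.has_layer(layer_name):
        g.add_layer(layer_name)
    fetched = src.fetch(list(ids))
    for i in ids:
        rec = fetched.get(i)
        if rec is None:
            logger.warning("accession %r unknown to the protein source; bare node added", i)
            attrs = {"node_type": "protein"}
        else:
            attrs = {"node_type": "protein", **{c: rec.attributes.get(c, "") for c in columns}}
        if g.has_node(i):
            g.update_node_attributes(i, attrs)
        else:
            g.add_node(i, layer_name, attrs)
    for a, b in get_up_interactions(src, list(ids)):
        g.add_edge(a, b, {"source": "UniProt", "type": "direct"})
    return g


# ------------------------------------------------------------------------- merge
def get_upkb_db_relations(
    src: ProteinSource, db: DrugBankData, protein_ids: list, drug_ids: list
) -> list:
    """Merged drug–protein relations from both databases.

    Takes the union of the protein source's drug cross-references and
    DrugBank's four relation classes, restricted to ``drug ∈ drug_ids`` and
    ``protein ∈ protein_ids``; relations agreeing on
    ``(drug, protein, relation_type)`` collapse to one with the union of
    their source sets.
    """
    drugs, prots = set(drug_ids), set(protein_ids)
    merged: dict = {}
    for rel in list(get_upkb_to_db(src, list(protein_ids))) + list(
        get_db_to_upkb(db, list(drug_ids), "all")
    ):
        if rel.drugbank_id not in drugs or rel.uniprot_id not in prots:
            continue
        if rel.key in merged:
            prev = merged[rel.key]
            merged[rel.key] = DrugProteinRelation(
                rel.drugbank_id, rel.uniprot_id, rel.relation_type, prev.sources | rel.sources
            )
        else:
            merged[rel.key] = rel
    return list(merged.values())


def connect_drug_protein(g: MultilayerGraph, relations: list) -> MultilayerGraph:
    """Add one edge per relation between its drug and protein nodes.

    Relations of different types between the same pair become parallel
    edges; the ``source`` attribute is the sorted comma-joined source set.
    Relations with a missing endpoint are skipped with a warning.
    """
    for rel in relations:
        if not (g.has_node(rel.drugbank_id) and g.has_node(rel.uniprot_id)):
            logger.warning(
                "relation %s—%s skipped: endpoint not in graph", rel.drugbank_id, rel.uniprot_id
            )
            continue
        g.add_edge(
            rel.drugbank_id,
            rel.uniprot_id,
            {
                "relation_type": rel.relation_type,
                "source": ",".join(sorted(rel.sources)),
                "type": "direct",
            },
        )
    return g


def build_multipath(
    name: str,
    src: ProteinSource,
    protein_ids: list,
    columns: list,
    db: DrugBankData,
    drug_ids: list,
) -> MultilayerGraph:
    """One-call orchestration: new graph → Protein layer → Drug layer →
    merged drug–protein connections."""
    from .core import new_graph
    from .drugbank import add_drug_layer

    g = new_graph(name)
    add_protein_layer(g, src, protein_ids, columns)
    add_drug_layer(g, db, drug_ids)
    relations = get_upkb_db_relations(src, db, protein_ids, drug_ids)
    connect_drug_protein(g, relations)
    return g
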