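"""Optional end-to-end demo on user-supplied files (not part of the tests).

Converts a real BioPAX pathway into a multilayer graph, generates a view by
deleting one layer transitively, undoes it, and — when DrugBank XML and a
protein TSV are supplied — integrates Drug and Protein layers with merged
drug–protein relations. Network access is never required: download the OWL
export manually, and obtain the (licensed) DrugBank XML yourself.

Example:
    python scripts/demo_pathway_workflow.py --owl wnt.owl --delete-layer RNA \
        --drugbank full_database.xml --proteins proteins.tsv
"""

from __future__ import annotations

import argparse

import pathlayers as pl
from pathlayers import drugbank, uniprot


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--owl", required=True, help="BioPAX OWL file")
    ap.add_argument("--pathway", default=None, help="pathway id (default: first in file)")
    ap.add_argument("--delete-layer", default="RNA", help="layer to delete in the view demo")
    ap.add_argument("--drugbank", default=None, help="DrugBank-dialect XML (optional)")
    ap.add_argument("--proteins", default=None, help="offline protein TSV (optional)")
    args = ap.parse_args()

    model = pl.read_biopax(args.owl)
    pathways = pl.list_pathways(model)
    print(f"{len(pathways)} pathway(s):")
    for pid, name in pathways[:10]:
        print(f"  {pid}\t{name}")
    pid = args.pathway or pathways[0][0]

    g = pl.pathway_to_multilayer(model, pid)
    print(g)

    v = pl.create_view(g)
    if g.has_layer(args.delete_layer):
        pl.add_step(v, "remove", "layer", args.delete_layer, {"transitive": True})
        print(pl.view_summary(v))
        pl.undo(v, 1)
        print("undo restores original:", pl.graphs_equal(v.current, v.original))
    else:
        print(f"(no layer named {args.delete_layer!r}; skipping view demo)")

    if args.drugbank and args.proteins:
        db = drugbank.load_db_xml(args.drugbank)
        src = uniprot.load_protein_table(args.proteins)
        protein_nodes = [n for n in g.nodes("Protein")] if g.has_layer("Protein") else []
        inst_ids = [n.attributes.get("biopax_id", "") for n in protein_nodes]
        accessions = pl.get_external_ids(model, [i for i in inst_ids if i], "UniProt")
        protein_ids = sorted({acc for accs in accessions.values() for acc in accs})
        rels = uniprot.get_upkb_to_db(src, protein_ids)
        drug_ids = sorted({r.drugbank_id for r in rels} & set(db.drugs))
        uniprot.add_protein_layer(g, src, protein_ids)
        drugbank.add_drug_layer(g, db, drug_ids)
        merged = uniprot.get_upkb_db_relations(src, db, protein_ids, drug_ids)
        uniprot.connect_drug_protein(g, merged)
        print(f"after integration: {g}")
        print(f"  {len(drug_ids)} drugs, {len(merged)} merged drug-protein relations")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
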