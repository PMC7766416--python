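# pathlayers

Multilayer pathway graphs with reversible edit provenance.

## The problem

Biological pathways — the curated webs of reactions, complexes and
regulatory controls that databases such as Reactome distribute in the
BioPAX OWL standard — are routinely simplified before analysis: a layer of
uninteresting molecule types is dropped, drug–target knowledge is bolted
on, nodes are pruned. Those edits are rarely recorded, which makes the
resulting network figures and analyses hard to reproduce. `pathlayers` is a
library and CLI for building pathway networks whose *every modification is
a recorded, undoable step*.

It does four things:

1. **Reads BioPAX Level 2/3 OWL** (RDF/XML) into a flat instance table and
   converts one pathway into a **multilayer graph**: nodes are the physical
   entities, partitioned into one layer per class (Protein, Complex, DNA,
   RNA, SmallMolecule, with bare physical entities on a catch-all
   PhysicalEntity layer); edges are derived from the interactions
   (left×right for conversions, controller→products for controls, component
   membership for complexes) and carry their source and interaction id.
2. **Records provenance**: a *view* pairs a deep snapshot of the original
   graph with its current state and an ordered list of steps
   (add/remove × node/edge/layer). `undo(view, n)` inverts the most recent
   `n` steps exactly — removing a whole layer is one step, and undoing it
   re-adds the layer, its nodes and all their connections.
3. **Derives transitive edges**: deleting a node (or a layer, cascading)
   can connect each pair of its surviving neighbors with an edge annotated
   `via=<deleted node>`, so the connectivity the node mediated is preserved
   and the simplification stays interpretable.
4. **Integrates drug and protein knowledge**: a DrugBank-dialect XML file
   (user-supplied; the full database is licensed) yields drugs, drug–drug
   interactions and the four drug→protein relation classes (target,
   enzyme, carrier, transporter); an offline UniProt-style TSV (or a
   batched online adapter, ≤50 ids per query) yields protein records,
   protein–protein interactions and protein→drug cross-references. Merged
   relations record which database(s) assert them, and parallel edges keep
   distinct relation types apart.

Everything the package reads can also be *generated*: `pathlayers.fixtures`
emits seeded synthetic BioPAX/DrugBank/TSV inputs together with manifests
of the expected outcome, so the whole pipeline is testable offline.

## Worked example

```python
import pathlayers as pl
from pathlayers import fixtures

spec = pl.FixtureSpec(seed=11, n_proteins=6, n_complexes=2, n_rna=2,
                      n_reactions=5, n_controls=2)
path, manifest = fixtures.gen_biopax(spec, "demo.owl")

model = pl.read_biopax(path)
print(pl.list_pathways(model))
g = pl.pathway_to_multilayer(model, "Pathway1")
print(g)

v = pl.create_view(g)
pl.add_step(v, "remove", "layer", "RNA", {"transitive": True})
print(pl.view_summary(v))
pl.undo(v, 1)
print("restored:", pl.graphs_equal(v.current, v.original))
```

prints

```
[('Pathway1', 'Fixture pathway 1')]
MultilayerGraph('Pathway1': 5 layers, 12 nodes, 13 edges)
view 2afe012ab86f
  created:  2026-09-21T17:20:49.125276+00:00
  modified: 2026-09-21T17:20:49.125869+00:00
  original: 5 layers, 12 nodes, 13 edges
  current:  4 layers, 10 nodes, 12 edges
  1 steps
  [1] remove layer 'RNA' (-2 nodes, -5 edges, +4 transitive)
restored: True
```

The 12 entities of the synthetic pathway occupy 5 layers; deleting the RNA
layer removes its 2 nodes and their 5 edges in **one** step, adds 4
transitive edges bridging the neighbors the RNA nodes used to connect, and
`undo` restores the original graph exactly.

The same flows are available from the shell:

```sh
pathlayers convert --input demo.owl --pathway list
pathlayers convert --input demo.owl --pathway Pathway1 --out g.graphml
pathlayers view --graph g.graphml --steps steps.json --out view.json
pathlayers undo --view view.json --undo 1 --out restored.json
pathlayers integrate --drugbank drugbank.xml --proteins proteins.tsv \
    --drug-ids drugs.txt --protein-ids prots.txt --out merged.graphml
```

For a real pathway, download the OWL export from Reactome manually (or via
`download_pathway(..., allow_network=True)`) and pass it to `convert`;
`scripts/demo_pathway_workflow.py` runs the full convert→view→integrate
workflow on user-supplied files.

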