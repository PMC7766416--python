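# Methods

## The multilayer pathway model

A pathway is modelled as an undirected, attributed multigraph whose nodes
are partitioned into named layers, one layer per node. Layers correspond to
BioPAX physical-entity classes: `Protein`, `Complex`, `DNA` (Dna and
DnaRegion), `RNA` (Rna and RnaRegion), `SmallMolecule`, and a catch-all
`PhysicalEntity` layer for bare physical entities and unmapped classes
(e.g. Gene). The class→layer map is overridable (`LayerPartitionRule`;
CLI `--layer-rule`). Layers are created lazily in first-touch order, so
only populated layers exist; layer ids are integers assigned sequentially
and never reused after deletion, so references recorded in provenance
payloads stay unambiguous.

Edges are undirected for identity (BioPAX rarely commits to a direction at
the graph level; where a conversion has one, it survives in edge
attributes). Parallel edges between the same pair are distinguished by an
integer key and differing attributes — e.g. one `target` and one `enzyme`
relation between the same drug and protein. Three attribute keys are
reserved: `source` (the database or file asserting the edge), `type`
(`direct`/`transitive`) and `via` (for transitive edges, the deleted node
that induced them); `type="transitive"` and a nonempty `via` imply each
other and are validated on insertion.

## BioPAX reading

The reader is a document-order RDF/XML scanner (lxml): every element in a
BioPAX Level 2/3 namespace carrying `rdf:about`/`rdf:ID` becomes one
instance; only `rdf:resource` references and literal children are
interpreted, and reified OWL axioms are ignored. This shallow reading is
deliberate — public pathway exports are flat ("striped") RDF/XML, and
document order lets pathway lists and xref lists preserve file order.
Level 2 spellings (`protein`, `LEFT`, `PATHWAY-COMPONENTS`, ...) are
canonicalised to Level 3 names at read time so everything downstream is
level-agnostic. Unknown classes in the BioPAX namespace are kept and
flagged `foreign`, never dropped. Dangling references are skipped with a
logged warning rather than failing, because real exports are frequently
imperfect. An independent RDF parser (rdflib) is used in the test suite as
a cross-check on instance counts; it is never on the production path.

Pathway membership is the breadth-first closure over `pathwayComponent`
and participant properties (`left`, `right`, `controller`, `controlled`,
`component`, `participant`, plus `product`/`template` for template
reactions and `memberPhysicalEntity`). Sub-pathways are flattened: their
components join the parent's closure, but the sub-pathway itself becomes
neither node nor edge. This was an open choice (exclusion was the
alternative); flattening was picked because a figure of "the pathway"
should show everything the pathway transitively contains.

## Edge derivation

BioPAX describes n-ary interactions, not edges, so a binary reduction must
be chosen. The package's documented convention:

| interaction | edges |
|---|---|
| conversion (reaction, assembly, transport, degradation) | every left × every right |
| control (catalysis, modulation, ...) | controller × right of the controlled conversion (left if no right; all participants of a controlled non-conversion) |
| complex membership | each component — its complex |
| participant-only interaction | clique over participants |

Each derived edge records `interaction` (the interaction's id) and
`source` (the source file). Self-pairs are skipped. Interactions never
become nodes. Stoichiometry and cellular location are copied to node
attributes but ignored for topology.

Node names use the entity's display name, else its id. When one display
name is shared by several entities, **all** colliders are suffixed
`#<id>` — suffixing every collider (rather than only the second and later
ones) makes node naming independent of traversal order, which the
determinism and manifest-agreement properties rely on.

## Transitive edges on deletion

Removing a node with `transitive=True` adds, for every unordered pair of
its distinct former neighbors, one edge `type="transitive", via=<node>`
— unless an edge already connects the pair and deduplication is on. For a
degree-d node with mutually non-adjacent neighbors this is exactly
d(d−1)/2 edges. Self-loops never contribute neighbor pairs. Whether a
pre-existing direct edge suppresses the transitive edge is exposed as the
graph-level policy `transitive_dedupe` (default on — a single bridging
edge per pair keeps counts interpretable); with dedupe off, a parallel
edge is added, but one removal still adds at most one edge per pair.

Layer removal deletes the layer's nodes sequentially in insertion order
with cascading: a transitive edge created by an earlier removal can seed a
later one, so a path running through several deleted nodes still connects
its surviving endpoints. With dedupe on, the surviving edge *set* is
invariant under the removal order (property-tested over random
permutations); only the `via` labels depend on the order, which is fixed
to insertion order for determinism. The operation reports only the net
effect: original edges removed and transitive edges still present at the
end (intermediate transitive edges consumed by the cascade cancel out),
which is exactly what undo needs.

## Views, steps and undo

A view holds a deep snapshot (`original`), a working copy (`current`),
and an ordered step list. `add_step` applies the operation to a copy of
`current` and swaps it in only on success, so failed steps are atomic by
construction — the view is bitwise unchanged. Each step stores a
restoration payload (removed node with its incident edges and spawned
transitive edges; for a layer, all of them plus the layer id): enough to
invert the step given the state that follows it. A layer removal is one
step regardless of how many nodes and edges it deletes.

`undo(view, n)` inverts the latest `n` steps in reverse order. Because
inversion runs in strict reverse, each payload is applied against exactly
the post-step state, so multi-edge keys and the layer-id counter can be
restored to their precise pre-step values; this makes partial undo
followed by replaying the dropped transcript reproduce the pre-undo state
exactly. There is no redo: undone steps move to an audit list that is
persisted with the view (one JSON document embedding both graphs) but not
exposed as a redo stack. Step ids continue from the historical maximum
after undo rather than resetting. Timestamps are wall-clock UTC with an
injectable clock for deterministic tests. Undo targets only the most
recent `n` steps (not arbitrary ids) — reversing a middle step against a
later state is not generally well-defined.

## Drug and protein integration

The DrugBank reader consumes the documented XML dialect from a local file
only; the full database requires a license, so nothing is downloaded.
Drug–drug interactions are listed under both partners in the dump and are
deduplicated on the unordered pair; secondary ids resolve as aliases to
the primary record; drug–drug edges are restricted to pairs where both
endpoints were requested, so no edge dangles. The four drug→protein
relation classes are read from each relation's polypeptide UniProtKB
identifier; relations without one are skipped with a warning.

The protein source is offline by default — a TSV with an `accession`
column, arbitrary attribute columns, and semicolon-joined `interactions`
and `drugbank` lists — because hermetic, reproducible runs cannot depend
on a web service. The online adapter is a thin, injectable transport that
chunks queries into batches of at most 50 accessions (the web service's
recommended per-query maximum) and must agree with the offline answers on
the same records (property-tested).

Relations found in both databases are merged on
`(drug, protein, relation_type)` with their source sets unioned, and the
edge's `source` attribute is the sorted comma-joined set, so attribution
is deterministic. Relations of different types between the same pair stay
separate parallel edges. Keeping both copies instead of merging was the
open alternative; merge-with-source-union was chosen because a duplicated
edge carries no extra information once the source set is recorded.
Integration order is: protein layer, drug layer (nodes + drug–drug
edges), then drug–protein connections; `build_multipath` composes the
three and equals the manual composition by graph equality.

## Synthetic data

The fixture generators are first-class, tested code. `gen_biopax` writes
Level 3 RDF/XML exercising every entity class, conversions, controls,
complex components, UniProt xrefs, multiple pathways, sub-pathways, name
collisions and optional dangling references; `gen_drugbank_xml` and
`gen_protein_tsv` write the integration dialects, cross-consistent at a
controlled overlap rate so the merged-relation outcome is known in
advance. Each generator returns a manifest computed by naive nested-loop
counting that deliberately duplicates (rather than imports) the layer map
and naming rule, so manifests are an independent oracle for the reader
and transform. Default sizes are small (a handful of each entity class, a
few reactions) — big enough to populate every layer and exercise every
interaction kind while keeping each generated file a few KB.

What the fixtures do *not* emulate: real ontology quirks (entity
references spread across files, generics with `memberPhysicalEntity`
hierarchies, evidence codes), realistic degree distributions, and the
scale of a real pathway (hundreds of nodes). Passing tests therefore
demonstrate correctness of the mechanics — parsing, partitioning, edge
derivation, provenance, merging — on well-formed inputs, not robustness
to every malformation in public exports (dangling references and unknown
classes are covered; other defects fail loudly as format errors).

## Numerical and procedural choices

- Multi-edge keys: the next free integer from the current parallel count;
  identity in graph equality is key-insensitive (parallel edges compare as
  multisets of attribute maps).
- Graph equality: same layer (id, name) set, same nodes with equal
  attributes, same edge multiset with equal attributes.
- GraphML dialect: plain networkx GraphML with a graph-level `layers`
  table of `id:name` pairs (`;`-joined — `;` in layer names is not
  supported by this format; JSON has no such limit), node key `layer`,
  and the edge attribute `source` renamed `source_db` in the file.
- Empty pathway → empty graph with zero layers plus a warning, not an
  error; empty drug/protein id lists → empty layers, zero nodes.
- Degenerate removals (isolated node, empty layer) return empty change
  lists and record a normal, invertible step.
- Problem sizes in the acceptance script (200 op sequences × ≤20 steps,
  500 transitive-oracle cases, 100 permutations/seeds/graphs per check)
  were chosen so each property is exercised across a broad seed range
  while the whole script completes in seconds.

## Known limitations

- No OWL reasoning or BioPAX validation; nested anonymous individuals are
  read only if they carry `rdf:about`/`rdf:ID`.
- Directionality, stoichiometry and cellular location are annotations,
  not topology.
- Drug–drug interaction descriptions are kept only as edge attributes;
  product/dosage/structure data are out of scope.
- The online protein adapter ships without a concrete HTTP transport; any
  callable honouring the batch contract can be injected.
- Undo is linear (no branching or redo); comparing two views is done via
  graph equality and summaries, not a structural diff.
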