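"""BioPAX reader: instance table, pathway enumeration, closure, xrefs."""

import pytest

from pathlayers import FixtureSpec, biopax, errors, fixtures

BP3 = "http://www.biopax.org/release/biopax-level3.owl#"


def write_owl(tmp_path, body, ns=BP3, name="t.owl"):
    doc = (
        '<?xml version="1.0"?>\n'
        '<rdf:RDF xmlns:rdf="http://www.w3.org/1999/02/22-rdf-syntax-ns#"\n'
        '         xmlns:owl="http://www.w3.org/2002/07/owl#"\n'
        f'         xmlns:bp="{ns}">\n'
        '<owl:Ontology rdf:about="">'
        f'<owl:imports rdf:resource="{ns.rstrip("#")}"/></owl:Ontology>\n'
        f"{body}\n"
        "</rdf:RDF>\n"
    )
    path = tmp_path / name
    path.write_text(doc)
    return str(path)


MINIMAL = """
  <bp:Pathway rdf:about="#P1">
    <bp:displayName>Demo A</bp:displayName>
    <bp:pathwayComponent rdf:resource="#r1"/>
  </bp:Pathway>
  <bp:Protein rdf:about="#pa"><bp:displayName>A</bp:displayName></bp:Protein>
  <bp:Protein rdf:about="#pb"><bp:displayName>B</bp:displayName></bp:Protein>
  <bp:BiochemicalReaction rdf:about="#r1">
    <bp:left rdf:resource="#pa"/>
    <bp:right rdf:resource="#pb"/>
  </bp:BiochemicalReaction>
"""


class TestReadBiopax:
    def test_minimal_file(self, tmp_path):
        model = biopax.read_biopax(write_owl(tmp_path, MINIMAL))
        assert model.level == 3
        assert len(model.instances) == 4
        assert {i.cls for i in model.instances} == {"Pathway", "Protein", "BiochemicalReaction"}

    def test_empty_document(self, tmp_path):
        model = biopax.read_biopax(write_owl(tmp_path, ""))
        assert model.level == 3
        assert model.instances == []

    def test_missing_file(self, tmp_path):
        with pytest.raises(errors.InputError):
            biopax.read_biopax(str(tmp_path / "nope.owl"))

    def test_not_xml(self, tmp_path):
        p = tmp_path / "bad.owl"
        p.write_text("this is not xml <")
        with pytest.raises(errors.FormatError):
            biopax.read_biopax(str(p))

    def test_unsupported_namespace(self, tmp_path):
        path = write_owl(tmp_path, "", ns="http://example.org/not-biopax#")
        with pytest.raises(errors.UnsupportedLevelError):
            biopax.read_biopax(path)

    def test_foreign_class_kept_and_flagged(self, tmp_path):
        body = MINIMAL + '<bp:FooEntity rdf:about="#weird"/>'
        model = biopax.read_biopax(write_owl(tmp_path, body))
        foo = model.get("weird")
        assert foo is not None and foo.foreign
        assert all(not i.foreign for i in model.instances if i.cls != "FooEntity")

    def test_level2_canonicalised(self, tmp_path):
        body = """
          <bp:pathway rdf:about="#pw">
            <bp:NAME>Old pathway</bp:NAME>
            <bp:PATHWAY-COMPONENTS rdf:resource="#rx"/>
          </bp:pathway>
          <bp:protein rdf:about="#p1"><bp:NAME>P one</bp:NAME></bp:protein>
          <bp:protein rdf:about="#p2"><bp:NAME>P two</bp:NAME></bp:protein>
          <bp:biochemicalReaction rdf:about="#rx">
            <bp:LEFT rdf:resource="#p1"/>
            <bp:RIGHT rdf:resource="#p2"/>
          </bp:biochemicalReaction>
        """
        model = biopax.read_biopax(
            write_owl(tmp_path, body, ns="http://www.biopax.org/release/biopax-level2.owl#")
        )
        assert model.level == 2
        assert {i.cls for i in model.instances} == {"Pathway", "Protein", "BiochemicalReaction"}
        ents, inters = biopax.pathway_components(model, "pw")
        assert {e.id for e in ents} == {"p1", "p2"}
        assert [i.id for i in inters] == ["rx"]

    def test_fixture_round_trip_against_manifest(self, biopax_file):
        path, manifest = biopax_file
        model = biopax.read_biopax(path)
        assert model.level == manifest["level"]
        assert len(model.instances) == manifest["n_instances"]

    def test_cross_check_instance_count_with_rdflib(self, biopax_file):
        """Independent RDF parser agrees on the number of typed individuals."""
        rdflib = pytest.importorskip("rdflib")
        path, manifest = biopax_file
        g = rdflib.Graph()
        g.parse(path, format="xml")
        typed = {
            s
            for s, _, o in g.triples((None, rdflib.RDF.type, None))
            if str(o).startswith(BP3)
        }
        assert len(typed) == manifest["n_instances"]


class TestPathways:
    def test_list_pathways_in_file_order(self, tmp_path):
        body = MINIMAL + '<bp:Pathway rdf:about="#P2"><bp:displayName>Demo B</bp:displayName></bp:Pathway>'
        model = biopax.read_biopax(write_owl(tmp_path, body))
        assert biopax.list_pathways(model) == [("P1", "Demo A"), ("P2", "Demo B")]

    def test_no_pathways(self, tmp_path):
        model = biopax.read_biopax(write_owl(tmp_path, "<bp:Protein rdf:about='#p'/>"))
        assert biopax.list_pathways(model) == []

    def test_nested_subpathway_both_listed(self, tmp_path):
        spec = FixtureSpec(seed=5, include_subpathway=True)
        path, _ = fixtures.gen_biopax(spec, str(tmp_path / "sub.owl"))
        model = biopax.read_biopax(path)
        ids = [pid for pid, _ in biopax.list_pathways(model)]
        assert "Pathway1" in ids and "SubPathway1" in ids


class TestComponents:
    def test_reaction_closure(self, tmp_path):
        model = biopax.read_biopax(write_owl(tmp_path, MINIMAL))
        ents, inters = biopax.pathway_components(model, "P1")
        assert {e.id for e in ents} == {"pa", "pb"}
        assert [i.id for i in inters] == ["r1"]

    def test_control_closure(self, tmp_path):
        body = MINIMAL + """
          <bp:Protein rdf:about="#pc"><bp:displayName>C</bp:displayName></bp:Protein>
          <bp:Catalysis rdf:about="#ctrl">
            <bp:controller rdf:resource="#pc"/>
            <bp:controlled rdf:resource="#r1"/>
          </bp:Catalysis>
        """
        # the control reaches the pathway through pathwayComponent
        body = body.replace(
            "<bp:pathwayComponent rdf:resource=\"#r1\"/>",
            "<bp:pathwayComponent rdf:resource=\"#r1\"/><bp:pathwayComponent rdf:resource=\"#ctrl\"/>",
        )
        model = biopax.read_biopax(write_owl(tmp_path, body))
        ents, inters = biopax.pathway_components(model, "P1")
        assert {e.id for e in ents} == {"pa", "pb", "pc"}
        assert {i.id for i in inters} == {"r1", "ctrl"}

    def test_non_pathway_id_rejected(self, tmp_path):
        model = biopax.read_biopax(write_owl(tmp_path, MINIMAL))
        with pytest.raises(errors.UnknownPathwayError):
            biopax.pathway_components(model, "pa")

    def test_closure_referenced_instances_are_returned(self, biopax_file):
        path, _ = biopax_file
        model = biopax.read_biopax(path)
        ents, inters = biopax.pathway_components(model, "Pathway1")
        known = {e.id for e in ents} | {i.id for i in inters}
        for inter in inters:
            for prop in ("left", "right", "controller", "controlled", "component"):
                for rid in inter.refs(prop):
                    assert rid in known

    def test_idempotent_and_subpathway_flattened(self, tmp_path):
        spec = FixtureSpec(seed=11, include_subpathway=True)
        path, manifest = fixtures.gen_biopax(spec, str(tmp_path / "sub.owl"))
        model = biopax.read_biopax(path)
        first = biopax.pathway_components(model, "Pathway1")
        second = biopax.pathway_components(model, "Pathway1")
        assert {e.id for e in first[0]} == {e.id for e in second[0]}
        assert len(first[0]) == manifest["n_entities"]
        assert len(first[1]) == manifest["n_interactions"]

    def test_dangling_reference_skipped(self, tmp_path):
        spec = FixtureSpec(seed=3, n_dangling=2)
        path, manifest = fixtures.gen_biopax(spec, str(tmp_path / "dangling.owl"))
        model = biopax.read_biopax(path)
        ents, _ = biopax.pathway_components(model, "Pathway1")
        assert len(ents) == manifest["n_entities"]


class TestExternalIds:
    def test_uniprot_lookup_and_empty(self, tmp_path):
        body = """
          <bp:Protein rdf:about="#p1"><bp:xref rdf:resource="#x1"/></bp:Protein>
          <bp:UnificationXref rdf:about="#x1">
            <bp:db>UniProtKB</bp:db><bp:id>P12345</bp:id>
          </bp:UnificationXref>
        """
        model = biopax.read_biopax(write_owl(tmp_path, body))
        assert biopax.get_external_ids(model, ["p1"], "UniProt") == {"p1": ["P12345"]}
        assert biopax.get_external_ids(model, ["p1"], "ChEBI") == {"p1": []}

    def test_multiple_xrefs_in_file_order(self, tmp_path):
        body = """
          <bp:Protein rdf:about="#p1">
            <bp:xref rdf:resource="#x1"/><bp:xref rdf:resource="#x2"/>
          </bp:Protein>
          <bp:UnificationXref rdf:about="#x1"><bp:db>uniprot knowledgebase</bp:db><bp:id>P1</bp:id></bp:UnificationXref>
          <bp:UnificationXref rdf:about="#x2"><bp:db>UniProtKB</bp:db><bp:id>P2</bp:id></bp:UnificationXref>
        """
        model = biopax.read_biopax(write_owl(tmp_path, body))
        assert biopax.get_external_ids(model, ["p1"], "uniprot") == {"p1": ["P1", "P2"]}

    def test_unknown_instance_yields_empty(self, tmp_path):
        model = biopax.read_biopax(write_owl(tmp_path, MINIMAL))
        assert biopax.get_external_ids(model, ["ghost"], "UniProt") == {"ghost": []}

    def test_fixture_accessions(self, biopax_file):
        path, manifest = biopax_file
        model = biopax.read_biopax(path)
        ids = list(manifest["uniprot_accessions"])
        got = biopax.get_external_ids(model, ids, "UniProt")
        assert got == {i: [manifest["uniprot_accessions"][i]] for i in ids}


class TestDownload:
    def test_network_disabled_by_default(self, tmp_path):
        with pytest.raises(errors.NetworkDisabledError):
            biopax.download_pathway("R-HSA-195721", 3, str(tmp_path / "p.owl"))

    def test_bad_level(self, tmp_path):
        with pytest.raises(errors.ArgumentError):
            biopax.download_pathway("R-HSA-195721", 4, str(tmp_path / "p.owl"))
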