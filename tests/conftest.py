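import pytest

from pathlayers import FixtureSpec, fixtures, new_graph


@pytest.fixture
def star_graph():
    """Center c adjacent to u1..u4, no other edges."""
    g = new_graph("star")
    g.add_layer("Hub")
    g.add_layer("Spoke")
    g.add_node("c", "Hub")
    for i in range(1, 5):
        g.add_node(f"u{i}", "Spoke")
        g.add_edge("c", f"u{i}")
    return g


@pytest.fixture
def toy_three_layer():
    """Small 3-layer graph used by view/step tests."""
    g = new_graph("toy")
    for layer in ("Protein", "RNA", "Complex"):
        g.add_layer(layer)
    g.add_node("P1", "Protein")
    g.add_node("P2", "Protein")
    g.add_node("R1", "RNA")
    g.add_node("C1", "Complex")
    g.add_edge("P1", "P2", {"source": "fix"})
    g.add_edge("P1", "R1")
    g.add_edge("R1", "C1")
    return g


@pytest.fixture
def biopax_file(tmp_path):
    spec = FixtureSpec(seed=7)
    path, manifest = fixtures.gen_biopax(spec, str(tmp_path / "fixture.owl"))
    return path, manifest


@pytest.fixture
def drugbank_file(tmp_path):
    spec = FixtureSpec(seed=7)
    path, manifest = fixtures.gen_drugbank_xml(spec, str(tmp_path / "drugbank.xml"))
    return path, manifest


@pytest.fixture
def protein_file(tmp_path):
    spec = FixtureSpec(seed=7)
    path, manifest = fixtures.gen_protein_tsv(spec, str(tmp_path / "proteins.tsv"))
    return path, manifest
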