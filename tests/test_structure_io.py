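import numpy as np
import pytest

from hbstrand import structure_io
from hbstrand.structure_io import (
    ManifestEntry,
    SelectionError,
    StructureParseError,
    apply_selector,
    classify_chains,
    parse_protein_selector,
    parse_structure,
    read_manifest,
)
from hbstrand.synthetic_data import structure_to_pdb


def test_fixture_round_trip_preserves_chains_and_coordinates(simple_fixture, tmp_path):
    _, structure, _, _ = simple_fixture
    path = tmp_path / "fx.pdb"
    path.write_text(structure_to_pdb(structure))
    parsed = parse_structure(path)
    assert [c.chain_id for c in parsed.chains] == [c.chain_id for c in structure.chains]
    roles = {r.chain_id: r.role for r in classify_chains(parsed)}
    assert roles == {"A": "protein", "B": "dna", "C": "dna"}
    for orig_chain, new_chain in zip(structure.chains, parsed.chains):
        for orig_res, new_res in zip(orig_chain.residues, new_chain.residues):
            assert len(orig_res.atoms) == len(new_res.atoms)
            for a, b in zip(orig_res.atoms, new_res.atoms):
                assert np.allclose(a.pos, b.pos, atol=1e-3)


def test_altloc_resolution_keeps_highest_occupancy(tmp_path):
    lines = [
        "ATOM      1  N  AALA A   1      11.000  12.000  13.000  0.60 10.00           N",
        "ATOM      2  N  BALA A   1      15.000  16.000  17.000  0.40 10.00           N",
        "ATOM      3  CA  ALA A   1      12.000  12.500  13.500  1.00 10.00           C",
        "END",
    ]
    path = tmp_path / "altloc.pdb"
    path.write_text("\n".join(lines) + "\n")
    st = parse_structure(path)
    n_atom = st.chain("A").residues[0].atom("N")
    assert np.allclose(n_atom.pos, [11.0, 12.0, 13.0])
    assert n_atom.altloc == "A"


def test_input_hydrogens_are_discarded(tmp_path):
    lines = [
        "ATOM      1  N   ALA A   1      11.000  12.000  13.000  1.00 10.00           N",
        "ATOM      2  H   ALA A   1      11.500  12.500  13.500  1.00 10.00           H",
        "END",
    ]
    path = tmp_path / "h.pdb"
    path.write_text("\n".join(lines) + "\n")
    st = parse_structure(path)
    assert [a.name for a in st.chain("A").residues[0].atoms] == ["N"]


def test_parse_errors_for_missing_or_bad_file(tmp_path):
    with pytest.raises(StructureParseError):
        parse_structure(tmp_path / "nope.pdb")
    bad = tmp_path / "empty.pdb"
    bad.write_text("REMARK nothing here\n")
    with pytest.raises(StructureParseError):
        parse_structure(bad)


def test_chain_role_classification(simple_fixture):
    _, structure, _, _ = simple_fixture
    roles = {r.chain_id: r.role for r in classify_chains(structure)}
    assert roles["A"] == "protein"
    assert roles["B"] == "dna" and roles["C"] == "dna"


def test_water_only_chain_is_other(tmp_path):
    lines = [
        "HETATM    1  O   HOH W   1      11.000  12.000  13.000  1.00 10.00           O",
        "HETATM    2  O   HOH W   2      14.000  15.000  16.000  1.00 10.00           O",
        "END",
    ]
    path = tmp_path / "wat.pdb"
    path.write_text("\n".join(lines) + "\n")
    roles = classify_chains(parse_structure(path))
    assert roles[0].role == "other"


@pytest.mark.parametrize(
    "selector,expected",
    [("A", ("A", None)), ("D:3-226", ("D", (3, 226))), (" B : 4-53 ".replace(" ", ""), ("B", (4, 53)))],
)
def test_protein_selector_parsing(selector, expected):
    assert parse_protein_selector(selector) == expected


def _entry(chain="A", rng=None, scope="chain"):
    return ManifestEntry(
        pdb_id="syn", group="HS", protein_chain=chain,
        residue_range=rng, dna_chain_ids=("B", "C"), scope=scope,
    )


def test_domain_selection_restricts_and_chain_is_superset(simple_fixture):
    _, structure, _, _ = simple_fixture
    chain_unit = apply_selector(structure, _entry())
    dom_unit = apply_selector(structure, _entry(rng=(2, 4), scope="domain"))
    dom_nums = {r.seq_num for r in dom_unit.protein_residues}
    chain_nums = {r.seq_num for r in chain_unit.protein_residues}
    assert dom_nums == {n for n in chain_nums if 2 <= n <= 4}
    assert dom_nums <= chain_nums


def test_selector_errors(simple_fixture):
    _, structure, _, _ = simple_fixture
    with pytest.raises(SelectionError):
        apply_selector(structure, _entry(chain="Z"))
    with pytest.raises(SelectionError):
        apply_selector(structure, _entry(rng=(900, 999), scope="domain"))


def test_manifest_round_trip(tmp_path):
    text = (
        "pdb_id\tgroup\tprotein_selector\tdna_chains\tscope\n"
        "2e52\tMS\tD:3-226\tE,F\tdomain\n"
        "4abt\tHS\tA\tE,H\tchain\n"
    )
    path = tmp_path / "manifest.tsv"
    path.write_text(text)
    entries = read_manifest(path)
    assert entries[0].pdb_id == "2e52"
    assert entries[0].residue_range == (3, 226)
    assert entries[1].dna_chain_ids == ("E", "H")
    assert entries[1].group == "HS"


def test_manifest_rejects_bad_rows(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("pdb_id\tgroup\tprotein_selector\tdna_chains\tscope\nx\tZZ\tA\tB,C\tchain\n")
    with pytest.raises(ValueError):
        read_manifest(path)
    path.write_text("pdb_id\tgroup\tprotein_selector\tdna_chains\tscope\nx\tHS\tA\tB\tchain\n")
    with pytest.raises(ValueError):
        read_manifest(path)


def test_find_structure_file(tmp_path):
    (tmp_path / "1abc.pdb").write_text("END\n")
    assert structure_io.find_structure_file(tmp_path, "1ABC").endswith("1abc.pdb")
    assert structure_io.find_structure_file(tmp_path, "2xyz") is None
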