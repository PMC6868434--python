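import json

import numpy as np
import pytest

from hbstrand._geometry import distance
from hbstrand.dna_model import detect_base_pairs
from hbstrand.structure_io import parse_structure
from hbstrand.synthetic_data import (
    FixtureSpec,
    ProbeSpec,
    build_fixture,
    generate_bdna,
    plant_probe,
    random_fixture_spec,
    write_fixture,
)


def test_generate_bdna_basic_shape():
    s1, s2 = generate_bdna("GAATTC")
    assert len(s1) == len(s2) == 6
    assert [r.res_name for r in s1] == ["DG", "DA", "DA", "DT", "DT", "DC"]
    assert [r.res_name for r in s2] == ["DG", "DA", "DA", "DT", "DT", "DC"]  # palindrome
    assert {r.chain_id for r in s1} == {"B"}
    assert {r.chain_id for r in s2} == {"C"}


def test_single_base_duplex():
    s1, s2 = generate_bdna("G")
    duplex = detect_base_pairs(s1, s2)
    assert len(duplex.pairs) == 1 and duplex.pairs[0].pair_type == "GC"


def test_fiber_regularity_of_c1_distances():
    s1, _ = generate_bdna("ACGTACGTAC")
    steps = [
        distance(s1[i].atom("C1'").pos, s1[i + 1].atom("C1'").pos)
        for i in range(len(s1) - 1)
    ]
    assert max(steps) - min(steps) < 0.1


def test_invalid_sequence_rejected():
    with pytest.raises(ValueError):
        generate_bdna("GAXTC")
    with pytest.raises(ValueError):
        generate_bdna("")


def test_plant_probe_rejects_unavailable_groove_atom():
    s1, s2 = generate_bdna("GAATTC")
    with pytest.raises(ValueError):
        plant_probe(s1, ProbeSpec(strand=1, base_index=0, groove="sideways"), 1)


def test_write_fixture_is_deterministic(tmp_path):
    spec = random_fixture_spec(17)
    p1, j1, _, _ = write_fixture(spec, tmp_path / "a")
    p2, j2, _, _ = write_fixture(spec, tmp_path / "b")
    assert open(p1, "rb").read() == open(p2, "rb").read()
    assert open(j1, "rb").read() == open(j2, "rb").read()


def test_fixture_round_trips_and_truth_json_is_consistent(tmp_path):
    spec = FixtureSpec(
        dna_sequence="GAATTC",
        probes=[
            ProbeSpec(strand=1, base_index=0, groove="major"),
            ProbeSpec(strand=2, base_index=5, groove="major"),
        ],
        seed=3,
    )
    pdb_path, json_path, structure, gt = write_fixture(spec, tmp_path)
    parsed = parse_structure(pdb_path)
    assert [c.chain_id for c in parsed.chains] == ["A", "B", "C"]
    payload = json.load(open(json_path))
    assert payload["n_scb_strand1"] == gt.n_scb_strand1 == 1
    assert payload["n_scb_strand2"] == 1
    assert payload["is_5050_bonds"] is True
    assert payload["base_pair_hbonds"] == [
        {"strand1_seq": 1, "strand2_seq": 6, "pair_type": "GC"}
    ]
    # engaged pairs are a subset of the duplex's Watson-Crick pairs
    duplex = detect_base_pairs(structure.chain("B").residues, structure.chain("C").residues)
    pair_keys = {(p.res_i.seq_num, p.res_j.seq_num) for p in duplex.pairs}
    for bp in payload["base_pair_hbonds"]:
        assert (bp["strand1_seq"], bp["strand2_seq"]) in pair_keys


def test_ground_truth_arithmetic():
    spec = FixtureSpec(
        dna_sequence="GCGCGCGCGCGC",
        probes=[
            ProbeSpec(strand=1, base_index=0, groove="major"),
            ProbeSpec(strand=1, base_index=4, groove="major"),
            ProbeSpec(strand=1, base_index=8, groove="major"),
            ProbeSpec(strand=2, base_index=1, groove="major"),
            ProbeSpec(strand=1, base_index=2, groove="minor", outcome="near_miss_distance"),
        ],
        seed=5,
    )
    _, gt = build_fixture(spec)
    assert (gt.n_scb_strand1, gt.n_scb_strand2) == (3, 1)
    assert gt.pct_dominant == pytest.approx(75.0)
    assert gt.dominant_strand == 1
    assert not gt.is_5050_bonds
    assert gt.n_scb_major_s1 == 3 and gt.n_scb_minor_s1 == 0  # near-miss not counted


def test_random_specs_are_valid_and_seeded():
    s1 = random_fixture_spec(5)
    s2 = random_fixture_spec(5)
    assert s1 == s2
    n = len(s1.dna_sequence)
    for p in s1.probes:
        assert 0 <= p.base_index < n
        assert p.groove in ("major", "minor")
        assert p.outcome in ("bond", "near_miss_distance", "near_miss_angle")


@pytest.mark.parametrize(
    "base_index,groove,probe_type",
    [
        (0, "major", "SER"),   # Ser OG -> DG O6
        (0, "major", "ASN"),   # Asn ND2 -> DG O6
        (0, "major", "ARG"),   # Arg guanidinium -> DG O6
        (5, "major", "ASP"),   # DC N4 -> Asp carboxylate
        (5, "major", "ASN"),   # DC N4 -> Asn OD1
        (1, "minor", "ASN"),   # Asn ND2 -> DA N3
    ],
)
def test_probe_chemistries_each_give_exactly_one_bond(base_index, groove, probe_type):
    from hbstrand.hbond_detect import detect_hbonds_energy, detect_hbonds_geometric
    from hbstrand.synthetic_data import fixture_unit

    spec = FixtureSpec(
        dna_sequence="GAATTC",
        probes=[ProbeSpec(strand=1, base_index=base_index, groove=groove, probe_type=probe_type)],
        seed=1,
    )
    structure, gt = build_fixture(spec)
    unit = fixture_unit(structure)
    assert len(gt.bonds) == 1
    for det in (detect_hbonds_geometric, detect_hbonds_energy):
        bonds = det(unit)
        scb = [b for b in bonds if b.interaction_class == "sidechain-base"]
        assert len(scb) == 1
        assert scb[0].groove == groove
        assert scb[0].dna_res.seq_num == base_index + 1


def test_backbone_probe_gives_sidechain_backbone_bond():
    from hbstrand.hbond_detect import detect_hbonds_geometric
    from hbstrand.synthetic_data import fixture_unit

    spec = FixtureSpec(
        dna_sequence="GAATTC",
        probes=[ProbeSpec(strand=1, base_index=2, groove="backbone")],
        seed=2,
    )
    structure, gt = build_fixture(spec)
    assert gt.n_nonscb_s1 == 1 and gt.n_scb_strand1 == 0
    bonds = detect_hbonds_geometric(fixture_unit(structure))
    assert len(bonds) == 1
    assert bonds[0].interaction_class == "sidechain-backbone"
    assert bonds[0].groove == "none"


def test_cohort_groups_differ_in_strand_balance():
    """The synthetic specificity groups reproduce their defining planted
    statistics: most NS complexes lack side chain-base bonds entirely, the
    MS group has a large one-strand-only fraction, and equal-contribution
    cases concentrate in the HS group."""
    from hbstrand.synthetic_data import cohort_specs

    stats = {}
    for group in ("HS", "MS", "NS"):
        specs = cohort_specs(group, seed=1)
        zero = eq = one = 0
        for sp in specs:
            _, gt = build_fixture(sp)
            total = gt.n_scb_strand1 + gt.n_scb_strand2
            if total == 0:
                zero += 1
            else:
                eq += gt.is_5050_bonds
                one += min(gt.n_scb_strand1, gt.n_scb_strand2) == 0
        stats[group] = (zero / len(specs), eq / max(1, len(specs) - zero), one / max(1, len(specs) - zero))
    assert stats["NS"][0] > 0.5  # mostly no side chain-base bonds at all
    assert stats["HS"][0] == 0.0
    assert stats["HS"][1] > stats["MS"][1]  # equal contribution favours HS
    assert stats["MS"][2] > stats["HS"][2]  # one-strand-only favours MS
    # determinism of the cohort
    assert cohort_specs("HS", seed=1)[:3] == cohort_specs("HS", seed=1)[:3]


def test_secstruct_segments_are_included_in_fixture():
    spec = FixtureSpec(
        dna_sequence="GAATTC",
        probes=[],
        secstruct_segments=[("helix", 10), ("coil", 5)],
        seed=1,
    )
    structure, gt = build_fixture(spec)
    assert structure.has_chain("P")
    assert gt.state3_labels == ["helix"] * 10 + ["coil"] * 5
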