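import numpy as np
import pytest

from helpers import detected_bond_keys, oracle_bond_keys
from hbstrand.hbond_detect import (
    DetectorParams,
    HydrogenBond,
    classify_hbond,
    detect_hbonds_energy,
    detect_hbonds_geometric,
    mayo_energy,
    place_polar_hydrogens,
)
from hbstrand.structure_io import Atom, Residue
from hbstrand.synthetic_data import (
    FixtureSpec,
    ProbeSpec,
    build_fixture,
    fixture_unit,
    random_fixture_spec,
)


def _res(chain, num, name, kind, atoms):
    r = Residue(chain_id=chain, seq_num=num, icode="", res_name=name, kind=kind)
    for aname, pos in atoms:
        r.atoms.append(Atom(name=aname, element=aname.strip("'")[0], pos=np.array(pos, float)))
    return r


# ---------------------------------------------------------------------------
# hydrogen placement
# ---------------------------------------------------------------------------

def test_asn_amide_hydrogens_in_plane():
    res = _res("A", 1, "ASN", "amino_acid", [
        ("CB", [-1.3, -0.9, 0.0]),
        ("CG", [0.0, -1.3, 0.0]),
        ("OD1", [1.1, -1.9, 0.0]),
        ("ND2", [0.0, 0.0, 0.0]),
    ])
    sites = place_polar_hydrogens([res], "protein")
    nd2 = [s for s in sites if s.atom.name == "ND2"]
    assert len(nd2) == 1 and len(nd2[0].h_positions) == 2
    for h in nd2[0].h_positions:
        assert abs(np.linalg.norm(h - nd2[0].atom.pos) - 1.00) < 0.01
        assert abs(h[2]) < 1e-6  # in the amide plane


def test_ser_hydroxyl_aims_at_nearby_acceptor():
    res = _res("A", 1, "SER", "amino_acid", [("CB", [-1.41, 0, 0]), ("OG", [0, 0, 0])])
    acceptor = np.array([2.2, 1.8, 0.3])
    sites = place_polar_hydrogens([res], "protein", acceptor_positions=[acceptor])
    h = sites[0].h_positions[0]
    oh = h - res.atom("OG").pos
    aim = acceptor - res.atom("OG").pos
    cosang = np.dot(oh, aim) / (np.linalg.norm(oh) * np.linalg.norm(aim))
    assert np.degrees(np.arccos(cosang)) < 15.0


def test_ser_hydroxyl_staggers_without_acceptor():
    res = _res("A", 1, "SER", "amino_acid", [("CB", [-1.41, 0, 0]), ("OG", [0, 0, 0])])
    sites = place_polar_hydrogens([res], "protein", acceptor_positions=[])
    h = sites[0].h_positions[0]
    assert abs(np.linalg.norm(h - res.atom("OG").pos) - 0.96) < 0.01


def test_donor_with_missing_antecedent_is_skipped():
    res = _res("A", 1, "SER", "amino_acid", [("OG", [0, 0, 0])])  # no CB
    assert place_polar_hydrogens([res], "protein") == []


# ---------------------------------------------------------------------------
# Mayo 12-10 energy
# ---------------------------------------------------------------------------

def test_mayo_energy_minimum_is_minus_v0():
    assert mayo_energy(2.8, 1.0) == pytest.approx(-8.0, abs=1e-12)


def test_mayo_energy_vanishes_at_long_range():
    assert abs(mayo_energy(10.0, 1.0)) < 0.01


def test_mayo_energy_matches_closed_form_at_3_2():
    # independent evaluation of V0*(5 r^12 - 6 r^10), r = 2.8/3.2
    r = 2.8 / 3.2
    expected = 8.0 * (5.0 * r**12 - 6.0 * r**10)
    assert mayo_energy(3.2, 1.0) == pytest.approx(expected, rel=1e-12)
    assert expected < -4.0  # still a deep well at 3.2 A


def test_mayo_energy_rejects_nonpositive_distance():
    with pytest.raises(ValueError):
        mayo_energy(0.0, 1.0)


# ---------------------------------------------------------------------------
# detection on planted probes
# ---------------------------------------------------------------------------

def _single_probe_unit(groove="major", outcome="bond", base_index=0, strand=1, seq="GAATTC"):
    spec = FixtureSpec(
        dna_sequence=seq,
        probes=[ProbeSpec(strand=strand, base_index=base_index, groove=groove, outcome=outcome)],
        seed=7,
    )
    structure, gt = build_fixture(spec)
    return fixture_unit(structure), gt


def test_planted_bond_found_by_both_detectors():
    unit, _ = _single_probe_unit()
    for det in (detect_hbonds_geometric, detect_hbonds_energy):
        bonds = det(unit)
        assert len(bonds) == 1
        hb = bonds[0]
        assert hb.interaction_class == "sidechain-base"
        assert hb.groove == "major"
        assert hb.dna_chain_id == "B"
    e_bond = detect_hbonds_energy(unit)[0]
    assert e_bond.energy is not None and e_bond.energy <= -0.6


def test_distance_near_miss_rejected_then_recovered_by_loosening():
    unit, _ = _single_probe_unit(outcome="near_miss_distance")
    assert detect_hbonds_geometric(unit) == []
    assert detect_hbonds_energy(unit) == []
    loose = DetectorParams(max_da=4.5, max_ha=3.3)
    assert len(detect_hbonds_geometric(unit, loose)) == 1


def test_angle_near_miss_rejected_by_both_detectors():
    unit, _ = _single_probe_unit(outcome="near_miss_angle", base_index=2)
    assert detect_hbonds_geometric(unit) == []
    assert detect_hbonds_energy(unit) == []


def test_energy_cutoff_monotonicity():
    unit, _ = _single_probe_unit(outcome="near_miss_distance")
    # the 4.2 A placement is below any plausible cutoff magnitude ...
    strict = detect_hbonds_energy(unit, DetectorParams(method="energy", energy_cutoff=-0.6))
    loose = detect_hbonds_energy(unit, DetectorParams(method="energy", energy_cutoff=-0.01))
    assert detected_bond_keys(strict) <= detected_bond_keys(loose)
    # ... and a loose cutoff recovers it
    assert len(loose) == 1
    assert -0.6 < loose[0].energy <= -0.01


def test_geometric_max_da_monotonicity(simple_fixture):
    _, _, _, unit = simple_fixture
    n_by_cutoff = [
        len(detect_hbonds_geometric(unit, DetectorParams(max_da=d)))
        for d in (3.9, 3.5, 3.1, 2.7)
    ]
    assert n_by_cutoff == sorted(n_by_cutoff, reverse=True)


def test_clear_cut_geometric_bonds_found_by_energy_detector(simple_fixture):
    _, _, _, unit = simple_fixture
    geo = [
        hb
        for hb in detect_hbonds_geometric(unit)
        if hb.d_da <= 3.2 and hb.theta_dha >= 150.0
    ]
    energy_keys = detected_bond_keys(detect_hbonds_energy(unit))
    assert geo and detected_bond_keys(geo) <= energy_keys


def test_no_bond_connects_one_molecule(simple_fixture):
    _, _, _, unit = simple_fixture
    for det in (detect_hbonds_geometric, detect_hbonds_energy):
        for hb in det(unit):
            kinds = {hb.donor_res.kind, hb.acceptor_res.kind}
            assert kinds == {"amino_acid", "nucleotide"}


@pytest.mark.parametrize("seed", [2, 11, 23, 57])
def test_detectors_match_brute_force_oracle(seed):
    structure, _ = build_fixture(random_fixture_spec(seed))
    unit = fixture_unit(structure)
    for method, det in (("geometric", detect_hbonds_geometric), ("energy", detect_hbonds_energy)):
        assert detected_bond_keys(det(unit)) == oracle_bond_keys(unit, method)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def _classify(prot_atoms, prot_name, dna_atoms, dna_name, donor_is_protein=True):
    prot = _res("A", 1, prot_name, "amino_acid", prot_atoms)
    dna = _res("B", 1, dna_name, "nucleotide", dna_atoms)
    if donor_is_protein:
        hb = HydrogenBond(
            donor_res=prot, donor_atom=prot.atoms[0],
            acceptor_res=dna, acceptor_atom=dna.atoms[0],
            h_pos=None, d_da=2.9, d_ha=None, theta_dha=None, energy=None,
        )
    else:
        hb = HydrogenBond(
            donor_res=dna, donor_atom=dna.atoms[0],
            acceptor_res=prot, acceptor_atom=prot.atoms[0],
            h_pos=None, d_da=2.9, d_ha=None, theta_dha=None, energy=None,
        )
    return classify_hbond(hb)


def test_classification_matrix():
    hb = _classify([("NH1", [0, 0, 0])], "ARG", [("O6", [2.9, 0, 0])], "DG")
    assert (hb.interaction_class, hb.groove) == ("sidechain-base", "major")
    hb = _classify([("N", [0, 0, 0])], "ARG", [("OP1", [2.9, 0, 0])], "DG")
    assert (hb.interaction_class, hb.groove) == ("mainchain-backbone", "none")
    hb = _classify([("OG", [0, 0, 0])], "SER", [("O4'", [2.9, 0, 0])], "DG")
    assert (hb.interaction_class, hb.groove) == ("sidechain-backbone", "none")
    hb = _classify([("OD1", [0, 0, 0])], "ASN", [("N6", [2.9, 0, 0])], "DA", donor_is_protein=False)
    assert (hb.interaction_class, hb.groove) == ("sidechain-base", "major")
    assert hb.dna_chain_id == "B"
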