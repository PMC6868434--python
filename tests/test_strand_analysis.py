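import dataclasses

import pytest

from hbstrand.dna_model import detect_base_pairs
from hbstrand.hbond_detect import detect_hbonds_energy, detect_hbonds_geometric
from hbstrand.strand_analysis import (
    ComplexSummary,
    SummaryError,
    find_basepair_hbonds,
    summarize_complex,
    summarize_group,
)
from hbstrand.structure_io import AnalysisUnit, ManifestEntry
from hbstrand.synthetic_data import (
    FixtureSpec,
    ProbeSpec,
    build_fixture,
    fixture_unit,
)


def _summary_for(spec, detector="geometric"):
    structure, gt = build_fixture(spec)
    unit = fixture_unit(structure)
    duplex = detect_base_pairs(unit.dna_strand1, unit.dna_strand2)
    det = detect_hbonds_geometric if detector == "geometric" else detect_hbonds_energy
    bonds = det(unit)
    return summarize_complex(bonds, duplex, unit.entry, detector=detector), gt, unit, duplex, bonds


def _probes(n1, n2, length):
    """bond probes on n1 distinct strand-1 bases (pair steps 0, 2, ...) and
    n2 strand-2 bases (pair steps from the far end), so geometries stay
    independent."""
    probes = [ProbeSpec(strand=1, base_index=2 * i, groove="major") for i in range(n1)]
    # strand-2 residue index k sits at pair step length-1-k
    probes += [ProbeSpec(strand=2, base_index=2 * j, groove="major") for j in range(n2)]
    return probes


def test_equal_counts_make_a_5050_case():
    spec = FixtureSpec(dna_sequence="GCATGCATGCAT", probes=_probes(3, 3, 12), seed=1)
    cs, gt, *_ = _summary_for(spec)
    assert (cs.n_scb_strand1, cs.n_scb_strand2) == (3, 3)
    assert cs.pct_dominant == pytest.approx(50.0)
    assert cs.is_5050_bonds
    assert cs.dominant_strand == 1  # deterministic tie-break


def test_unequal_counts_give_dominant_strand_percentage():
    spec = FixtureSpec(dna_sequence="GCATGCATGCATGC", probes=_probes(3, 1, 14), seed=2)
    cs, *_ = _summary_for(spec)
    assert (cs.n_scb_strand1, cs.n_scb_strand2) == (3, 1)
    assert cs.dominant_strand == 1
    assert cs.pct_dominant == pytest.approx(75.0)
    assert not cs.is_5050_bonds


def test_one_strand_only_case():
    spec = FixtureSpec(dna_sequence="GCATGCATGCAT", probes=_probes(4, 0, 12), seed=3)
    cs, *_ = _summary_for(spec)
    assert cs.one_strand_only
    assert cs.pct_dominant == pytest.approx(100.0)


def test_summary_matches_planted_truth_for_both_detectors(simple_fixture):
    spec, structure, gt, unit = simple_fixture
    duplex = detect_base_pairs(unit.dna_strand1, unit.dna_strand2)
    for detector, det in (("geometric", detect_hbonds_geometric), ("energy", detect_hbonds_energy)):
        cs = summarize_complex(det(unit), duplex, unit.entry, detector=detector)
        assert (cs.n_scb_strand1, cs.n_scb_strand2) == (gt.n_scb_strand1, gt.n_scb_strand2)
        assert sorted(k[1] for k in cs.engaged_bases_s1) == gt.engaged_bases_s1
        assert sorted(k[1] for k in cs.engaged_bases_s2) == gt.engaged_bases_s2
        got_pairs = sorted((p.res_i.seq_num, p.res_j.seq_num, p.pair_type) for p in cs.bp_hb)
        want_pairs = sorted(
            (p["strand1_seq"], p["strand2_seq"], p["pair_type"]) for p in gt.base_pair_hbonds
        )
        assert got_pairs == want_pairs


def test_basepair_hbonds_require_both_bases():
    # both bases of the terminal GC pair engaged -> the pair is returned
    spec = FixtureSpec(
        dna_sequence="GAATTC",
        probes=[
            ProbeSpec(strand=1, base_index=0, groove="major"),
            ProbeSpec(strand=2, base_index=5, groove="major"),
        ],
        seed=4,
    )
    cs, gt, unit, duplex, bonds = _summary_for(spec)
    assert len(cs.bp_hb) == 1 and cs.bp_hb[0].pair_type == "GC"
    assert cs.n_bp_hb_GC == 1 and cs.n_bp_hb_AT == 0
    # one engaged base per strand but on DIFFERENT pairs -> no engaged pair
    spec2 = FixtureSpec(
        dna_sequence="GAATTC",
        probes=[
            ProbeSpec(strand=1, base_index=0, groove="major"),
            ProbeSpec(strand=2, base_index=3, groove="major"),
        ],
        seed=5,
    )
    cs2, *_ = _summary_for(spec2)
    assert cs2.is_5050_bonds and cs2.bp_hb == []


def test_groove_filter_restricts_basepair_hbonds():
    spec = FixtureSpec(
        dna_sequence="GAATTC",
        probes=[
            ProbeSpec(strand=1, base_index=0, groove="major"),
            ProbeSpec(strand=2, base_index=5, groove="major"),
            ProbeSpec(strand=1, base_index=3, groove="minor"),
            ProbeSpec(strand=2, base_index=2, groove="minor"),
        ],
        seed=6,
    )
    cs, gt, unit, duplex, bonds = _summary_for(spec)
    assert len(find_basepair_hbonds(bonds, duplex, "both")) == 2
    assert len(find_basepair_hbonds(bonds, duplex, "major")) == 1
    assert len(find_basepair_hbonds(bonds, duplex, "minor")) == 1
    with pytest.raises(ValueError):
        find_basepair_hbonds(bonds, duplex, "sideways")


def test_strand_relabeling_symmetry(simple_fixture):
    spec, structure, gt, unit = simple_fixture
    duplex = detect_base_pairs(unit.dna_strand1, unit.dna_strand2)
    bonds = detect_hbonds_geometric(unit)
    cs = summarize_complex(bonds, duplex, unit.entry)
    swapped_entry = dataclasses.replace(unit.entry, dna_chain_ids=("C", "B"))
    swapped_unit = AnalysisUnit(
        structure=structure,
        entry=swapped_entry,
        protein_residues=unit.protein_residues,
        dna_strand1=unit.dna_strand2,
        dna_strand2=unit.dna_strand1,
    )
    duplex_sw = detect_base_pairs(swapped_unit.dna_strand1, swapped_unit.dna_strand2)
    cs_sw = summarize_complex(detect_hbonds_geometric(swapped_unit), duplex_sw, swapped_entry)
    assert cs.pct_dominant == pytest.approx(cs_sw.pct_dominant)
    assert cs.is_5050_bonds == cs_sw.is_5050_bonds
    assert cs.is_5050_bases_major == cs_sw.is_5050_bases_major
    assert (cs.n_scb_strand1, cs.n_scb_strand2) == (cs_sw.n_scb_strand2, cs_sw.n_scb_strand1)
    assert len(cs.bp_hb) == len(cs_sw.bp_hb)


def test_groove_counts_partition_strand_counts(simple_fixture):
    _, _, _, unit = simple_fixture
    duplex = detect_base_pairs(unit.dna_strand1, unit.dna_strand2)
    bonds = detect_hbonds_geometric(unit)
    cs = summarize_complex(bonds, duplex, unit.entry)
    none_s1 = sum(
        1 for hb in bonds
        if hb.is_sidechain_base and hb.groove == "none" and duplex.strand_of(hb.dna_res) == 1
    )
    none_s2 = sum(
        1 for hb in bonds
        if hb.is_sidechain_base and hb.groove == "none" and duplex.strand_of(hb.dna_res) == 2
    )
    assert cs.n_scb_strand1 == cs.n_scb_major_s1 + cs.n_scb_minor_s1 + none_s1
    assert cs.n_scb_strand2 == cs.n_scb_major_s2 + cs.n_scb_minor_s2 + none_s2


def test_energy_split_conserves_total(simple_fixture):
    _, _, _, unit = simple_fixture
    duplex = detect_base_pairs(unit.dna_strand1, unit.dna_strand2)
    bonds = detect_hbonds_energy(unit)
    cs = summarize_complex(bonds, duplex, unit.entry, detector="energy")
    total = sum(hb.energy for hb in bonds if hb.is_sidechain_base)
    assert cs.e_scb_s1 + cs.e_scb_s2 == pytest.approx(total)


def _cs(pdb_id, n1, n2, group="HS"):
    cs = ComplexSummary(pdb_id=pdb_id, group=group, detector="geometric")
    cs.n_scb_strand1, cs.n_scb_strand2 = n1, n2
    if n1 + n2:
        cs.pct_dominant = 100.0 * max(n1, n2) / (n1 + n2)
        cs.dominant_strand = 1 if n1 >= n2 else 2
        cs.is_5050_bonds = n1 == n2
    return cs


def test_group_summary_definitions():
    gs = summarize_group([_cs("a", 4, 4), _cs("b", 6, 2), _cs("c", 5, 0)])
    assert gs.n_complexes_with_scb == 3
    assert gs.n_equal_contribution == 1
    assert gs.n_dominant_le75 == 2  # 50% and 75% both qualify as "no more than 75%"
    assert gs.n_one_strand_only == 1
    assert gs.pct_dominant_sorted == [100.0, 75.0, 50.0]


def test_group_summary_handles_empty_and_scb_free_complexes():
    assert summarize_group([]).n_complexes_with_scb == 0
    gs = summarize_group([_cs("a", 0, 0), _cs("b", 2, 1)])
    assert gs.n_complexes == 2
    assert gs.n_complexes_with_scb == 1


def test_group_summary_rejects_mixed_groups():
    with pytest.raises(SummaryError):
        summarize_group([_cs("a", 1, 1, group="HS"), _cs("b", 1, 1, group="MS")])


def test_bonds_outside_duplex_raise():
    spec = FixtureSpec(
        dna_sequence="GAATTC",
        probes=[ProbeSpec(strand=1, base_index=0, groove="major")],
        seed=9,
    )
    structure, _ = build_fixture(spec)
    unit = fixture_unit(structure)
    bonds = detect_hbonds_geometric(unit)
    from hbstrand.synthetic_data import generate_bdna

    other1, other2 = generate_bdna("TTTT", chain_id_1="X", chain_id_2="Y")
    foreign = detect_base_pairs(other1, other2)
    entry = ManifestEntry("x", "HS", "A", None, ("B", "C"), "chain")
    with pytest.raises(Exception):
        summarize_complex(bonds, foreign, entry)
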