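"""Self-contained protein-DNA fixtures with planted ground truth.

``generate_bdna`` builds an idealized B-form duplex by fiber-model stacking
(rise 3.38 A, twist 36 deg per step) of standard-reference-frame base
geometries; the complementary strand is generated by the pair dyad, so every
constructed pair has canonical Watson-Crick geometry.  The sugar-phosphate
moiety is schematic (exact C1' anchor plus an approximate phosphate group):
base-edge geometry, which the hydrogen-bond analysis reads, is exact, while
backbone torsions are not modelled.

``plant_probe`` drops a free-floating amino-acid fragment (with backbone
stub) next to a chosen base-edge atom either at ideal hydrogen-bonding
geometry (outcome "bond": donor-acceptor 2.9 A, collinear approach) or
violating one criterion (near-miss outcomes: distance pushed to 4.2 A, or
the D-H-A angle collapsed below 90 deg).

``build_fixture``/``write_fixture`` assemble a complete complex (protein
chain A, DNA chains B and C) plus a machine-readable GroundTruth record,
and ``random_fixture_spec`` draws seeded random specs for property tests.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from ._geometry import rotate_about, unit
from .hbond_detect import _amide2_hydrogens, _bisector_hydrogen
from .structure_io import AnalysisUnit, Atom, Chain, ManifestEntry, Residue, Structure

RISE = 3.38
TWIST = 36.0

# Standard reference frame base-atom coordinates (A): x toward the major
# groove, y along the long pair axis, z = 0 base plane.  The complementary
# base of a pair is this table flipped through (x, -y, -z).
STD_BASE_XY: dict[str, dict[str, tuple[float, float]]] = {
    "DA": {
        "N9": (-1.291, 4.498), "C8": (0.024, 4.897), "N7": (0.877, 3.902),
        "C5": (0.071, 2.771), "C6": (0.369, 1.398), "N6": (1.611, 0.909),
        "N1": (-0.668, 0.532), "C2": (-1.912, 1.023), "N3": (-2.320, 2.290),
        "C4": (-1.267, 3.124), "C1'": (-2.479, 5.346),
    },
    "DG": {
        "N9": (-1.289, 4.551), "C8": (0.023, 4.962), "N7": (0.870, 3.969),
        "C5": (0.071, 2.833), "C6": (0.424, 1.460), "O6": (1.554, 0.955),
        "N1": (-0.700, 0.641), "C2": (-1.999, 1.087), "N2": (-2.949, 0.139),
        "N3": (-2.342, 2.364), "C4": (-1.265, 3.177), "C1'": (-2.477, 5.399),
    },
    "DC": {
        "N1": (-1.285, 4.542), "C2": (-1.472, 3.158), "O2": (-2.628, 2.709),
        "N3": (-0.391, 2.344), "C4": (0.837, 2.868), "N4": (1.875, 2.027),
        "C5": (1.056, 4.275), "C6": (-0.023, 5.068), "C1'": (-2.477, 5.402),
    },
    "DT": {
        "N1": (-1.284, 4.500), "C2": (-1.462, 3.135), "O2": (-2.562, 2.608),
        "N3": (-0.298, 2.407), "C4": (0.994, 2.897), "O4": (1.944, 2.119),
        "C5": (1.106, 4.338), "C7": (2.466, 4.961), "C6": (-0.024, 5.057),
        "C1'": (-2.481, 5.354),
    },
}
# schematic phosphate, strand I local frame (radius ~8.9 A)
PHOSPHATE_LOCAL = {
    "P": (-4.20, 7.90, 2.00),
    "OP1": (-5.20, 8.70, 2.60),
    "OP2": (-3.10, 8.70, 1.50),
}

COMPLEMENT_SEQ = {"A": "T", "T": "A", "G": "C", "C": "G"}
SEQ_TO_RES = {"A": "DA", "T": "DT", "G": "DG", "C": "DC"}

ELEMENT_OF = {"N": "N", "C": "C", "O": "O", "P": "P", "S": "S"}


def _element(atom_name: str) -> str:
    return ELEMENT_OF.get(atom_name.strip("'0123456789")[0], atom_name[0])


def _step_transform(i: int):
    def tf(p_local: np.ndarray) -> np.ndarray:
        rot = rotate_about(np.asarray(p_local, dtype=float), np.array([0.0, 0.0, 1.0]), TWIST * i)
        return rot + np.array([0.0, 0.0, RISE * i])

    return tf


def _base_atoms(res_name: str, flip: bool) -> list[tuple[str, np.ndarray]]:
    atoms = []
    for name, (x, y) in STD_BASE_XY[res_name].items():
        p = np.array([x, y, 0.0])
        if flip:
            p = np.array([x, -y, 0.0])
        atoms.append((name, p))
    for name, (x, y, z) in PHOSPHATE_LOCAL.items():
        p = np.array([x, y, z])
        if flip:
            p = np.array([x, -y, -z])
        atoms.append((name, p))
    return atoms


def generate_bdna(
    sequence: str, chain_id_1: str = "B", chain_id_2: str = "C"
) -> tuple[list[Residue], list[Residue]]:
    """Idealized B-DNA duplex for ``sequence`` (strand 1, 5'->3').

    Returns the two strands as residue lists; residue j of strand 2 pairs
    with residue n+1-j of strand 1.
    """
    sequence = sequence.upper()
    if not sequence:
        raise ValueError("empty sequence")
    bad = set(sequence) - set("ACGT")
    if bad:
        raise ValueError(f"invalid DNA characters: {sorted(bad)}")
    n = len(sequence)
    strand1: list[Residue] = []
    strand2_steps: list[Residue] = []
    for i, letter in enumerate(sequence):
        tf = _step_transform(i)
        res1 = Residue(chain_id=chain_id_1, seq_num=i + 1, icode="", res_name=SEQ_TO_RES[letter], kind="nucleotide")
        for name, p in _base_atoms(SEQ_TO_RES[letter], flip=False):
            res1.atoms.append(Atom(name=name, element=_element(name), pos=tf(p)))
        strand1.append(res1)
        comp = SEQ_TO_RES[COMPLEMENT_SEQ[letter]]
        res2 = Residue(chain_id=chain_id_2, seq_num=n - i, icode="", res_name=comp, kind="nucleotide")
        for name, p in _base_atoms(comp, flip=True):
            res2.atoms.append(Atom(name=name, element=_element(name), pos=tf(p)))
        strand2_steps.append(res2)
    strand2 = list(reversed(strand2_steps))  # 5'->3' order of the complement
    return strand1, strand2


# ---------------------------------------------------------------------------
# probe planting
# ---------------------------------------------------------------------------

#: per (base, groove): the targeted edge atom and whether the base side acts
#: as acceptor (probe donates) or donor (probe accepts)
TARGET_ATOM: dict[tuple[str, str], tuple[str, str]] = {
    ("DA", "major"): ("N6", "donor"),
    ("DG", "major"): ("O6", "acceptor"),
    ("DC", "major"): ("N4", "donor"),
    ("DT", "major"): ("O4", "acceptor"),
    ("DA", "minor"): ("N3", "acceptor"),
    ("DG", "minor"): ("N2", "donor"),
    ("DC", "minor"): ("O2", "acceptor"),
    ("DT", "minor"): ("O2", "acceptor"),
}

BOND_DISTANCE = 2.9
NEAR_MISS_DISTANCE = 4.2


@dataclass
class ProbeSpec:
    strand: int  # 1 | 2
    base_index: int  # 0-based index into the strand's residue list
    groove: str  # major | minor
    probe_type: Optional[str] = None  # SER/ASN/ARG for base acceptors, ASP/ASN for base donors
    outcome: str = "bond"  # bond | near_miss_distance | near_miss_angle


@dataclass
class FixtureSpec:
    dna_sequence: str
    probes: list[ProbeSpec] = field(default_factory=list)
    secstruct_segments: list[tuple[str, int]] = field(default_factory=list)
    seed: int = 0


@dataclass
class GroundTruth:
    """Planted truth for a fixture, written alongside the PDB file."""

    bonds: list[dict]  # donor/acceptor identities, class, groove, strand
    n_scb_strand1: int = 0
    n_scb_strand2: int = 0
    n_nonscb_s1: int = 0
    n_nonscb_s2: int = 0
    n_scb_major_s1: int = 0
    n_scb_major_s2: int = 0
    n_scb_minor_s1: int = 0
    n_scb_minor_s2: int = 0
    engaged_bases_s1: list[int] = field(default_factory=list)  # seq numbers
    engaged_bases_s2: list[int] = field(default_factory=list)
    engaged_bases_major_s1: list[int] = field(default_factory=list)
    engaged_bases_major_s2: list[int] = field(default_factory=list)
    dominant_strand: Optional[int] = None
    pct_dominant: Optional[float] = None
    is_5050_bonds: bool = False
    is_5050_bases_major: bool = False
    base_pair_hbonds: list[dict] = field(default_factory=list)  # both grooves
    base_pair_hbonds_major: list[dict] = field(default_factory=list)
    state3_labels: list[str] = field(default_factory=list)


def _base_frame(residue: Residue, target_atom: str):
    """(in-plane approach direction at the target atom, plane normal, atom).

    The approach direction follows the acceptor/donor lone-pair axis: the
    carbonyl extension for single-neighbour atoms (O6, O4, O2, amine N),
    the external ring bisector for two-neighbour atoms (N3, N7) -- so that
    a planted partner sees a wide, chemically sensible H-A-antecedent
    angle as well as satisfying the distance criteria.
    """
    ring = [a for a in residue.atoms if a.name in STD_BASE_XY[residue.res_name] and a.name != "C1'"]
    centroid = np.mean([a.pos for a in ring], axis=0)
    target = residue.atom(target_atom)
    v1 = ring[0].pos - centroid
    v2 = ring[2].pos - centroid
    normal = unit(np.cross(v1, v2))
    neighbours = [a for a in ring if a.name != target_atom and np.linalg.norm(a.pos - target.pos) < 1.7]
    if len(neighbours) >= 2:
        d = -(unit(neighbours[0].pos - target.pos) + unit(neighbours[1].pos - target.pos))
    elif neighbours:
        d = target.pos - neighbours[0].pos
    else:
        d = target.pos - centroid
    d_in_plane = d - np.dot(d, normal) * normal
    return unit(d_in_plane), normal, target


def _tail(start: np.ndarray, direction: np.ndarray, perp: np.ndarray, names: list[str]) -> list[tuple[str, np.ndarray]]:
    """Zig-zag backbone stub marching away from the DNA."""
    out = []
    for k, name in enumerate(names, start=1):
        pos = start + (1.45 * k) * direction + (0.55 * ((-1) ** k)) * perp
        out.append((name, pos))
    return out


def _theta_for_offset(beta_deg: float, d_da: float) -> float:
    """D-H-A angle when the N-H direction is rotated beta away from N->A."""
    a = np.array([d_da, 0.0, 0.0])
    h = np.array([np.cos(np.radians(180 - beta_deg)), np.sin(np.radians(180 - beta_deg)), 0.0])
    # H direction measured from donor at origin; 180-beta from +x = beta from -x... keep explicit:
    h = rotate_about(np.array([1.0, 0.0, 0.0]), np.array([0.0, 0.0, 1.0]), beta_deg)
    from ._geometry import angle_deg

    return angle_deg(np.zeros(3), h, a)


def _solve_beta(target_theta: float, d_da: float) -> float:
    """Rotation of the donor H away from the D->A axis giving the wanted
    D-H-A angle (bisection; theta decreases monotonically with beta)."""
    lo, hi = 0.0, 179.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _theta_for_offset(mid, d_da) > target_theta:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _plant_backbone_probe(
    residue: Residue, probe: ProbeSpec, seq_num: int, chain_id: str
) -> tuple[Residue, Optional[dict]]:
    """Asn amide donating into a phosphate oxygen: a non-side-chain-base
    contact (class sidechain-backbone, groove none) for affinity-style
    plantings."""
    from ._geometry import perpendicular

    op1 = residue.atom("OP1")
    p = residue.atom("P")
    if op1 is None or p is None:
        raise ValueError(f"{residue.label()} lacks phosphate atoms")
    d_hat = unit(op1.pos - p.pos)
    w_hat = perpendicular(d_hat)
    d_da = NEAR_MISS_DISTANCE if probe.outcome == "near_miss_distance" else BOND_DISTANCE
    res = Residue(chain_id=chain_id, seq_num=seq_num, icode="", res_name="ASN", kind="amino_acid")

    def add(name, pos):
        res.atoms.append(Atom(name=name, element=_element(name), pos=np.asarray(pos, float)))

    nd2 = op1.pos + d_da * d_hat
    u = rotate_about(-d_hat, w_hat, -120.0)
    cg = nd2 - 1.335 * u
    add("ND2", nd2)
    add("CG", cg)
    add("OD1", cg + 1.23 * rotate_about(u, w_hat, 120.0))
    cb = cg + 1.52 * rotate_about(u, w_hat, -120.0)
    add("CB", cb)
    for name, pos in _tail(cb, d_hat, w_hat, ["CA", "N", "C", "O"]):
        add(name, pos)
    expected = None
    if probe.outcome == "bond":
        expected = {
            "donor": f"{chain_id}/ASN{seq_num}/ND2",
            "acceptor": f"{residue.chain_id}/{residue.res_name}{residue.seq_num}/OP1",
            "class": "sidechain-backbone",
            "groove": "none",
            "strand": probe.strand,
            "dna_chain": residue.chain_id,
            "base_seq_num": residue.seq_num,
        }
    return res, expected


def plant_probe(
    strand_residues: list[Residue],
    probe: ProbeSpec,
    seq_num: int,
    chain_id: str = "A",
    partner_residues: Optional[list[Residue]] = None,
) -> tuple[Residue, Optional[dict]]:
    """Build the amino-acid fragment for one probe.

    Returns the probe residue and, for outcome "bond", the expected
    side chain-base hydrogen bond record (None for near-misses).
    """
    residue = strand_residues[probe.base_index]
    base = residue.base_name

    if probe.groove == "backbone":
        return _plant_backbone_probe(residue, probe, seq_num, chain_id)

    key = (base, probe.groove)
    if key not in TARGET_ATOM:
        raise ValueError(f"no groove edge atom for {base} in the {probe.groove} groove")
    target_name, base_role = TARGET_ATOM[key]
    d_hat, normal, target = _base_frame(residue, target_name)
    w_hat = unit(np.cross(d_hat, normal))  # in-plane->vertical rotation axis

    d_da = NEAR_MISS_DISTANCE if probe.outcome == "near_miss_distance" else BOND_DISTANCE

    probe_type = probe.probe_type
    if probe_type is None:
        if base_role == "acceptor":
            probe_type = "SER" if probe.outcome == "bond" else "ASN"
        else:
            probe_type = "ASP"

    res = Residue(chain_id=chain_id, seq_num=seq_num, icode="", res_name=probe_type, kind="amino_acid")

    def add(name: str, pos: np.ndarray) -> None:
        res.atoms.append(Atom(name=name, element=_element(name), pos=np.asarray(pos, dtype=float)))

    if base_role == "acceptor":
        # probe donates into the base acceptor along the outward direction
        aim = -d_hat  # donor->acceptor direction
        if probe.outcome == "near_miss_angle":
            beta = _solve_beta(60.0, d_da)
        else:
            beta = 0.0
        if probe_type == "SER":
            og = target.pos + d_da * d_hat
            add("OG", og)
            cb = og + 1.41 * rotate_about(d_hat, w_hat, -35.0)
            add("CB", cb)
            for name, pos in _tail(cb, d_hat, w_hat, ["CA", "N", "C", "O"]):
                add(name, pos)
        elif probe_type in ("ASN", "GLN"):
            nd2 = target.pos + d_da * d_hat
            h_dir = rotate_about(aim, w_hat, beta)
            u = rotate_about(h_dir, w_hat, -120.0)  # unit(ND2 - CG)
            cg = nd2 - 1.335 * u
            add("ND2", nd2)
            add("CG", cg)
            od1 = cg + 1.23 * rotate_about(u, w_hat, 120.0)
            add("OD1", od1)
            cb = cg + 1.52 * rotate_about(u, w_hat, -120.0)
            add("CB", cb)
            for name, pos in _tail(cb, d_hat, w_hat, ["CA", "N", "C", "O"]):
                add(name, pos)
            # construction check: the placement rule must reproduce the aim
            hs = _amide2_hydrogens(nd2, cg, od1)
            align = max(np.dot(unit(h - nd2), rotate_about(aim, w_hat, beta)) for h in hs)
            assert align > 0.999, "amide hydrogen not aligned with planted geometry"
        elif probe_type == "ARG":
            # guanidinium laid in the base plane; of the two chiralities,
            # keep the one whose NE/NH2 arm stays clearest of the DNA
            nh1 = target.pos + d_da * d_hat
            dna_atoms = np.array(
                [a.pos for r in strand_residues + (partner_residues or []) for a in r.atoms]
            )
            h_dir = rotate_about(aim, normal, beta)
            variants = []
            for sign in (1.0, -1.0):
                u = rotate_about(h_dir, normal, -sign * 120.0)
                cz = nh1 - 1.33 * u
                atoms = {
                    "NH1": nh1,
                    "CZ": cz,
                    "NH2": cz + 1.33 * rotate_about(u, normal, sign * 120.0),
                    "NE": cz + 1.33 * rotate_about(u, normal, -sign * 120.0),
                }
                atoms["CD"] = atoms["NE"] + 1.46 * rotate_about(
                    unit(atoms["NE"] - cz), normal, sign * 60.0
                )
                clearance = min(
                    float(np.min(np.linalg.norm(dna_atoms - p, axis=1)))
                    for n_, p in atoms.items()
                    if n_ != "NH1"
                )
                variants.append((clearance, sign, atoms))
            _, _, atoms = max(variants, key=lambda t: (t[0], t[1]))
            for name in ("NH1", "CZ", "NH2", "NE", "CD"):
                add(name, atoms[name])
            for name, pos in _tail(atoms["CD"], d_hat, w_hat, ["CB", "CA", "N", "C", "O"]):
                add(name, pos)
        else:
            raise ValueError(f"unsupported donor probe type {probe_type}")
    else:
        # base donates; probe supplies a carboxylate/amide acceptor along the
        # base amine's outward N-H direction
        ante = residue.atom({"N4": "C4", "N6": "C6", "N2": "C2"}[target_name])
        ref = next(a for a in residue.atoms if a.name not in (target_name, ante.name) and np.linalg.norm(a.pos - ante.pos) < 1.6)
        hs = _amide2_hydrogens(target.pos, ante.pos, ref.pos)
        h_dirs = [unit(h - target.pos) for h in hs]
        # the groove-facing amine hydrogen: of the two in-plane hydrogens,
        # one points into the Watson-Crick interface (at the partner base),
        # the other into the groove -- keep the one clear of the partner
        if partner_residues:
            partner_atoms = np.array([a.pos for r in partner_residues for a in r.atoms])

            def clearance(h):
                probe_pos = target.pos + BOND_DISTANCE * h
                return float(np.min(np.linalg.norm(partner_atoms - probe_pos, axis=1)))

            h_dir = max(h_dirs, key=clearance)
        else:
            h_dir = max(h_dirs, key=lambda h: np.dot(h, d_hat))
        if probe.outcome == "near_miss_angle":
            # rotate the acceptor in the base plane away from BOTH amine
            # hydrogens (offset >= ~75 deg from the groove-facing one, and
            # nearly anti from the Watson-Crick-facing one) so neither gives
            # an acceptable D-H-A angle; scan for the clearest placement
            other_h = h_dirs[1] if np.allclose(h_dirs[0], h_dir) else h_dirs[0]
            context = np.array(
                [a.pos for r in (strand_residues + (partner_residues or [])) for a in r.atoms]
            )
            candidates = []
            for beta in (75.0, 85.0, 95.0, 105.0):
                for sign in (1.0, -1.0):
                    cand = rotate_about(h_dir, normal, sign * beta)
                    if np.degrees(np.arccos(np.clip(np.dot(cand, other_h), -1, 1))) < 75.0:
                        continue
                    pos = target.pos + d_da * cand
                    clearance = float(np.min(np.linalg.norm(context - pos, axis=1)))
                    candidates.append((clearance, -beta, sign, cand))
            candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
            place_dir = candidates[0][3]
        else:
            place_dir = h_dir
        if probe_type not in ("ASP", "ASN"):
            raise ValueError(f"unsupported acceptor probe type {probe_type}")
        w2 = unit(np.cross(place_dir, normal))
        od1 = target.pos + d_da * place_dir
        if probe_type == "ASP":
            cg = od1 + 1.25 * rotate_about(-place_dir, w2, 120.0)
            add("OD1", od1)
            add("CG", cg)
            od2 = cg + 1.25 * rotate_about(unit(od1 - cg), w2, -120.0)
            add("OD2", od2)
            cb = cg + 1.52 * rotate_about(unit(od1 - cg), w2, 120.0)
            add("CB", cb)
        else:  # ASN acceptor side
            cg = od1 + 1.23 * rotate_about(-place_dir, w2, 120.0)
            add("OD1", od1)
            add("CG", cg)
            nd2 = cg + 1.335 * rotate_about(unit(od1 - cg), w2, -120.0)
            add("ND2", nd2)
            cb = cg + 1.52 * rotate_about(unit(od1 - cg), w2, 120.0)
            add("CB", cb)
        for name, pos in _tail(cb, d_hat, w_hat, ["CA", "N", "C", "O"]):
            add(name, pos)

    expected = None
    if probe.outcome == "bond":
        if base_role == "acceptor":
            donor_desc = {"SER": "OG", "ASN": "ND2", "GLN": "NE2", "ARG": "NH1"}[probe_type]
            expected = {
                "donor": f"{chain_id}/{probe_type}{seq_num}/{donor_desc}",
                "acceptor": f"{residue.chain_id}/{residue.res_name}{residue.seq_num}/{target_name}",
            }
        else:
            expected = {
                "donor": f"{residue.chain_id}/{residue.res_name}{residue.seq_num}/{target_name}",
                "acceptor": f"{chain_id}/{probe_type}{seq_num}/OD1",
            }
        expected.update(
            {
                "class": "sidechain-base",
                "groove": probe.groove,
                "strand": probe.strand,
                "dna_chain": residue.chain_id,
                "base_seq_num": residue.seq_num,
            }
        )
    return res, expected


# ---------------------------------------------------------------------------
# fixture assembly
# ---------------------------------------------------------------------------

def _ground_truth(
    spec: FixtureSpec, strand1: list[Residue], strand2: list[Residue], bonds: list[dict]
) -> GroundTruth:
    gt = GroundTruth(bonds=bonds)
    n = len(spec.dna_sequence)
    for b in [x for x in bonds if x["class"] != "sidechain-base"]:
        if b["strand"] == 1:
            gt.n_nonscb_s1 += 1
        else:
            gt.n_nonscb_s2 += 1
    bonds = [x for x in bonds if x["class"] == "sidechain-base"]
    for b in bonds:
        s = b["strand"]
        if s == 1:
            gt.n_scb_strand1 += 1
        else:
            gt.n_scb_strand2 += 1
        if b["groove"] == "major":
            if s == 1:
                gt.n_scb_major_s1 += 1
            else:
                gt.n_scb_major_s2 += 1
        elif b["groove"] == "minor":
            if s == 1:
                gt.n_scb_minor_s1 += 1
            else:
                gt.n_scb_minor_s2 += 1
    for s, all_attr, major_attr in (
        (1, "engaged_bases_s1", "engaged_bases_major_s1"),
        (2, "engaged_bases_s2", "engaged_bases_major_s2"),
    ):
        nums = sorted({b["base_seq_num"] for b in bonds if b["strand"] == s})
        setattr(gt, all_attr, nums)
        nums_major = sorted({b["base_seq_num"] for b in bonds if b["strand"] == s and b["groove"] == "major"})
        setattr(gt, major_attr, nums_major)
    n1, n2 = gt.n_scb_strand1, gt.n_scb_strand2
    if n1 + n2 > 0:
        gt.pct_dominant = 100.0 * max(n1, n2) / (n1 + n2)
        gt.dominant_strand = 1 if n1 >= n2 else 2
        gt.is_5050_bonds = n1 == n2
    m1, m2 = len(gt.engaged_bases_major_s1), len(gt.engaged_bases_major_s2)
    gt.is_5050_bases_major = m1 == m2 and m1 > 0
    # strand1 residue i+1 pairs with strand2 residue n-i
    for grooves, attr in ((("major", "minor"), "base_pair_hbonds"), (("major",), "base_pair_hbonds_major")):
        pairs = []
        s1_bases = {b["base_seq_num"] for b in bonds if b["strand"] == 1 and b["groove"] in grooves}
        s2_bases = {b["base_seq_num"] for b in bonds if b["strand"] == 2 and b["groove"] in grooves}
        for seq1 in sorted(s1_bases):
            seq2 = n - (seq1 - 1)
            if seq2 in s2_bases:
                letter = spec.dna_sequence[seq1 - 1]
                pair_type = "GC" if letter in "GC" else "AT"
                pairs.append({"strand1_seq": seq1, "strand2_seq": seq2, "pair_type": pair_type})
        setattr(gt, attr, pairs)
    return gt


def build_fixture(spec: FixtureSpec) -> tuple[Structure, GroundTruth]:
    """Assemble the complex in memory: protein chain A, DNA chains B and C."""
    strand1, strand2 = generate_bdna(spec.dna_sequence)
    probes: list[Residue] = []
    bonds: list[dict] = []
    for k, p in enumerate(spec.probes, start=1):
        strand = strand1 if p.strand == 1 else strand2
        partner = strand2 if p.strand == 1 else strand1
        res, expected = plant_probe(strand, p, seq_num=k, partner_residues=partner)
        probes.append(res)
        if expected is not None:
            bonds.append(expected)
    gt = _ground_truth(spec, strand1, strand2, bonds)
    if not probes:
        # a contact-free spectator residue keeps the protein chain present
        # (complexes without any side chain-base bond still have a protein)
        spectator = Residue(chain_id="A", seq_num=1, icode="", res_name="ALA", kind="amino_acid")
        for name, pos in (
            ("N", (60.0, 0.0, 0.0)), ("CA", (61.46, 0.0, 0.0)),
            ("C", (62.0, 1.42, 0.0)), ("O", (63.1, 1.6, 0.5)), ("CB", (61.9, -0.8, -1.2)),
        ):
            spectator.atoms.append(Atom(name=name, element=name[0], pos=np.array(pos)))
        probes = [spectator]
    chains = [Chain(chain_id="A", residues=probes)]
    chains.append(Chain(chain_id="B", residues=strand1))
    chains.append(Chain(chain_id="C", residues=strand2))
    if spec.secstruct_segments:
        pep = build_secstruct_peptide(spec.secstruct_segments, chain_id="P", offset=np.array([120.0, 0.0, 0.0]))
        chains.append(Chain(chain_id="P", residues=pep))
        gt.state3_labels = planted_state3_labels(spec.secstruct_segments)
    structure = Structure(name=f"synthetic-{spec.seed}", chains=chains)
    return structure, gt


def fixture_unit(structure: Structure, group: str = "HS", scope: str = "chain") -> AnalysisUnit:
    """ManifestEntry-equivalent view of a generated fixture."""
    entry = ManifestEntry(
        pdb_id=structure.name,
        group=group,
        protein_chain="A",
        residue_range=None,
        dna_chain_ids=("B", "C"),
        scope=scope,
    )
    protein = [r for r in structure.chain("A").residues] if structure.has_chain("A") else []
    return AnalysisUnit(
        structure=structure,
        entry=entry,
        protein_residues=protein,
        dna_strand1=list(structure.chain("B").residues),
        dna_strand2=list(structure.chain("C").residues),
    )


# ---------------------------------------------------------------------------
# PDB round trip
# ---------------------------------------------------------------------------

def _pdb_atom_line(serial: int, atom: Atom, res: Residue) -> str:
    name = atom.name
    if len(name) < 4 and len(atom.element) == 1:
        name = " " + name
    return (
        f"ATOM  {serial:5d} {name:<4.4s}{'':1s}{res.res_name:>3s} {res.chain_id:1s}"
        f"{res.seq_num:4d}{res.icode or ' ':1s}   "
        f"{atom.pos[0]:8.3f}{atom.pos[1]:8.3f}{atom.pos[2]:8.3f}"
        f"{atom.occupancy:6.2f}{0.0:6.2f}          {atom.element:>2s}"
    )


def structure_to_pdb(structure: Structure) -> str:
    lines = []
    serial = 1
    for chain in structure.chains:
        for res in chain.residues:
            for atom in res.atoms:
                lines.append(_pdb_atom_line(serial, atom, res))
                serial += 1
        lines.append(f"TER   {serial:5d}")
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_fixture(spec: FixtureSpec, directory: str | os.PathLike, stem: Optional[str] = None):
    """Write <stem>.pdb and <stem>.truth.json; returns (pdb_path, json_path,
    structure, ground_truth)."""
    structure, gt = build_fixture(spec)
    stem = stem or f"fixture_{spec.seed}"
    os.makedirs(directory, exist_ok=True)
    pdb_path = os.path.join(os.fspath(directory), stem + ".pdb")
    json_path = os.path.join(os.fspath(directory), stem + ".truth.json")
    with open(pdb_path, "w") as fh:
        fh.write(structure_to_pdb(structure))
    payload = asdict(gt)
    payload["spec"] = {
        "dna_sequence": spec.dna_sequence,
        "probes": [asdict(p) for p in spec.probes],
        "secstruct_segments": list(spec.secstruct_segments),
        "seed": spec.seed,
    }
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return pdb_path, json_path, structure, gt


# ---------------------------------------------------------------------------
# random specs for property tests
# ---------------------------------------------------------------------------

def random_fixture_spec(seed: int, min_len: int = 8, max_len: int = 14) -> FixtureSpec:
    """Seeded random fixture: a random duplex with non-clashing planted
    probes (fixed-geometry Asn/Asp fragments) and known per-strand truth.

    Probed pairs are kept >= 2 steps apart unless both bases of one pair are
    deliberately engaged, so planted geometries stay independent.
    """
    rng = np.random.default_rng(seed)
    n = int(rng.integers(min_len, max_len + 1))
    seq = "".join(rng.choice(list("ACGT"), size=n))
    probes: list[ProbeSpec] = []
    # candidate pair steps (0-based), spaced by >= 2
    steps = list(range(n))
    rng.shuffle(steps)
    chosen: list[int] = []
    for s in steps:
        if all(abs(s - c) >= 2 for c in chosen):
            chosen.append(s)
    n_probe_sites = min(len(chosen), int(rng.integers(1, 6)))
    for s in sorted(chosen[:n_probe_sites]):
        both = rng.random() < 0.3
        groove = "major" if rng.random() < 0.7 else "minor"
        outcome = "bond" if rng.random() < 0.8 else str(rng.choice(["near_miss_distance", "near_miss_angle"]))
        # strand1 index s <-> strand2 index n-1-s target the same pair
        which = int(rng.integers(1, 3))
        first = ProbeSpec(
            strand=which,
            base_index=s if which == 1 else n - 1 - s,
            groove=groove,
            probe_type=None,
            outcome=outcome,
        )
        # fixed-geometry fragments only, so each planted bond stands alone
        base1 = seq[s] if which == 1 else COMPLEMENT_SEQ[seq[s]]
        if TARGET_ATOM[(SEQ_TO_RES[base1], groove)][1] == "acceptor":
            first.probe_type = "ASN"
        probes.append(first)
        if both and outcome == "bond":
            other = 2 if which == 1 else 1
            second = ProbeSpec(
                strand=other,
                base_index=n - 1 - s if other == 2 else s,
                groove=groove,
                probe_type=None,
                outcome="bond",
            )
            base2 = COMPLEMENT_SEQ[base1]
            if TARGET_ATOM[(SEQ_TO_RES[base2], groove)][1] == "acceptor":
                second.probe_type = "ASN"
            probes.append(second)
    return FixtureSpec(dna_sequence=seq, probes=probes, seed=seed)


def _auto_probe(strand: int, base_index: int, groove: str, seq: str, n: int) -> ProbeSpec:
    """Bond probe with a fixed-geometry fragment (Asn for base acceptors,
    Asp for base donors) so planted bonds never depend on rotamer search."""
    if strand == 1:
        letter = seq[base_index]
    else:
        letter = COMPLEMENT_SEQ[seq[n - 1 - base_index]]
    probe = ProbeSpec(strand=strand, base_index=base_index, groove=groove)
    if TARGET_ATOM[(SEQ_TO_RES[letter], groove)][1] == "acceptor":
        probe.probe_type = "ASN"
    return probe


#: per-group planting statistics emulating the study conditions: highly
#: specific binders engage both strands nearly equally and often both bases
#: of a pair; multi-specific binders skew toward one strand; non-specific
#: binders mostly lack side chain-base bonds altogether
COHORT_SIZES = {"HS": 32, "MS": 115, "NS": 52}
_GROUP_CODE = {"HS": 1, "MS": 2, "NS": 3}


def cohort_spec(group: str, index: int, seed: int = 0) -> FixtureSpec:
    """Fixture spec for complex ``index`` of a synthetic specificity group."""
    if group not in COHORT_SIZES:
        raise ValueError(f"unknown group {group!r}")
    rng = np.random.default_rng([seed % (2**31), _GROUP_CODE[group], index])
    if group == "HS":
        diff = int(rng.choice([0, 1, 2], p=[0.34, 0.46, 0.20]))
        n2 = int(rng.integers(1, 4))
        n1 = n2 + diff
        n_pairs = int(min(n1, n2, rng.integers(0, 3)))
        p_major = 0.85
    elif group == "MS":
        if rng.random() < 0.38:
            n2 = 0
            n1 = int(rng.integers(1, 6))
        else:
            n2 = int(rng.integers(1, 3))
            n1 = n2 + int(rng.integers(1, 4))
        n_pairs = 1 if (min(n1, n2) > 0 and rng.random() < 0.1) else 0
        p_major = 0.75
    else:  # NS
        if rng.random() < 34.0 / 52.0:
            n1 = n2 = 0
        else:
            n1 = int(rng.integers(0, 2))
            n2 = int(rng.integers(0, 2) if n1 else 1)
        n_pairs = 0
        p_major = 0.2
    # backbone (phosphate) contacts: affinity-style, roughly strand-balanced
    # in every group
    bb1 = int(rng.integers(0, 3))
    bb2 = int(rng.integers(0, 3))
    n_sites = (n1 - n_pairs) + (n2 - n_pairs) + n_pairs + bb1 + bb2
    length = max(12, 2 * n_sites + 4) + int(rng.integers(0, 3))
    seq = "".join(rng.choice(list("ACGT"), size=length))
    steps = [s for s in range(0, length, 2)]
    rng.shuffle(steps)
    probes: list[ProbeSpec] = []
    it = iter(steps)
    for _ in range(n_pairs):
        s = next(it)
        groove = "major"  # engaged pairs read the major groove
        probes.append(_auto_probe(1, s, groove, seq, length))
        probes.append(_auto_probe(2, length - 1 - s, groove, seq, length))
    for _ in range(n1 - n_pairs):
        s = next(it)
        groove = "major" if rng.random() < p_major else "minor"
        probes.append(_auto_probe(1, s, groove, seq, length))
    for _ in range(n2 - n_pairs):
        s = next(it)
        groove = "major" if rng.random() < p_major else "minor"
        probes.append(_auto_probe(2, length - 1 - s, groove, seq, length))
    for strand, count in ((1, bb1), (2, bb2)):
        for _ in range(count):
            s = next(it)
            idx = s if strand == 1 else length - 1 - s
            probes.append(ProbeSpec(strand=strand, base_index=idx, groove="backbone"))
    return FixtureSpec(dna_sequence=seq, probes=probes, seed=int(rng.integers(0, 2**31)))


def cohort_specs(group: str, seed: int = 0, n: Optional[int] = None) -> list[FixtureSpec]:
    n = COHORT_SIZES[group] if n is None else n
    return [cohort_spec(group, i, seed) for i in range(n)]


# ---------------------------------------------------------------------------
# ideal-geometry peptides for secondary-structure fixtures
# ---------------------------------------------------------------------------

_BOND = {"N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329, "C-O": 1.231}
_ANGLE = {"C-N-CA": 121.7, "N-CA-C": 111.2, "CA-C-N": 116.2, "CA-C-O": 120.8}

PHI_PSI = {"helix": (-57.0, -47.0), "strand": (-119.0, 113.0), "coil": (-75.0, 145.0)}


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float, angle: float, dihedral: float) -> np.ndarray:
    """Place atom d from three predecessors by internal coordinates."""
    bc = unit(c - b)
    n = unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    ang = np.radians(angle)
    dih = np.radians(dihedral)
    d2 = np.array(
        [
            -bond * np.cos(ang),
            bond * np.sin(ang) * np.cos(dih),
            bond * np.sin(ang) * np.sin(dih),
        ]
    )
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def build_peptide(
    phi_psi: list[tuple[float, float]],
    chain_id: str = "P",
    start_seq: int = 1,
    res_name: str = "ALA",
    offset: Optional[np.ndarray] = None,
) -> list[Residue]:
    """Poly-Ala backbone (N, CA, C, O [+CB]) from a phi/psi list."""
    n_res = len(phi_psi)
    coords: list[dict[str, np.ndarray]] = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_BOND["N-CA"], 0.0, 0.0])
    ang = np.radians(_ANGLE["N-CA-C"])
    c0 = ca0 + _BOND["CA-C"] * np.array([-np.cos(ang), np.sin(ang), 0.0])
    coords.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n_res):
        phi_prev, psi_prev = phi_psi[i - 1]
        prev = coords[-1]
        n_i = _nerf(prev["N"], prev["CA"], prev["C"], _BOND["C-N"], _ANGLE["CA-C-N"], psi_prev)
        ca_i = _nerf(prev["CA"], prev["C"], n_i, _BOND["N-CA"], _ANGLE["C-N-CA"], 180.0)
        phi_i = phi_psi[i][0]
        c_i = _nerf(prev["C"], n_i, ca_i, _BOND["CA-C"], _ANGLE["N-CA-C"], phi_i)
        coords.append({"N": n_i, "CA": ca_i, "C": c_i})
    # carbonyl O anti to the next N (trans peptide)
    for i in range(n_res):
        psi_i = phi_psi[i][1]
        cur = coords[i]
        cur["O"] = _nerf(cur["N"], cur["CA"], cur["C"], _BOND["C-O"], _ANGLE["CA-C-O"], psi_i + 180.0)
    out = []
    offset = np.zeros(3) if offset is None else np.asarray(offset, dtype=float)
    for i, atom_map in enumerate(coords):
        res = Residue(chain_id=chain_id, seq_num=start_seq + i, icode="", res_name=res_name, kind="amino_acid")
        for name in ("N", "CA", "C", "O"):
            res.atoms.append(Atom(name=name, element=name[0], pos=atom_map[name] + offset))
        out.append(res)
    return out


def build_helix(n_res: int = 12, chain_id: str = "P", start_seq: int = 1, offset=None) -> list[Residue]:
    return build_peptide([PHI_PSI["helix"]] * n_res, chain_id=chain_id, start_seq=start_seq, offset=offset)


def build_sheet(
    n_res: int = 6, chain_id: str = "P", start_seq: int = 1, offset=None
) -> list[Residue]:
    """Two-strand antiparallel beta sheet as one chain with a break.

    The second strand is the first rotated 180 deg about the strand axis
    and translated so the canonical antiparallel O...H-N ladder forms; the
    placement is refined numerically against the 2.9 A O...N target.
    """
    from scipy.optimize import minimize

    s1 = build_peptide([PHI_PSI["strand"]] * n_res, chain_id=chain_id, start_seq=start_seq)
    cas = np.array([r.atom("CA").pos for r in s1])
    axis = unit(cas[-1] - cas[0])
    center = cas.mean(axis=0)
    # pleat normal: average local normal of CA triplets
    normals = []
    for i in range(1, len(cas) - 1):
        v = np.cross(cas[i - 1] - cas[i], cas[i + 1] - cas[i])
        if np.linalg.norm(v) > 1e-6:
            normals.append(unit(v) * (1 if i % 2 else -1))
    sheet_perp = unit(np.cross(axis, np.mean(normals, axis=0)))

    def place(params):
        shift = center + params[0] * sheet_perp + params[1] * axis + params[2] * np.mean(normals, axis=0)
        placed = []
        for r in s1:
            atoms = {}
            for a in r.atoms:
                p = rotate_about(a.pos - center, axis, 180.0)
                atoms[a.name] = p + shift
            placed.append(atoms)
        return placed

    # antiparallel register: residue i of strand 1 with residue i of the
    # flipped copy (the flip reverses the running direction in space)
    def loss(params):
        placed = place(params)
        total = 0.0
        for i in range(0, n_res):
            j = i
            total += (np.linalg.norm(s1[i].atoms[3].pos - placed[j]["N"]) - 2.9) ** 2
            total += (np.linalg.norm(placed[j]["O"] - s1[i].atoms[0].pos) - 2.9) ** 2
        return total

    best = min(
        (
            minimize(loss, x0, method="Nelder-Mead", options={"xatol": 1e-4, "fatol": 1e-8, "maxiter": 2000})
            for x0 in ([4.8, 0.0, 0.0], [-4.8, 0.0, 0.0], [4.8, 1.0, 0.5], [-4.8, -1.0, -0.5])
        ),
        key=lambda r: r.fun,
    )
    placed = place(best.x)
    out = list(s1)
    offset_vec = np.zeros(3) if offset is None else np.asarray(offset, dtype=float)
    for j, atoms in enumerate(placed):
        res = Residue(
            chain_id=chain_id,
            seq_num=start_seq + n_res + 4 + j,  # numbering gap marks the break
            icode="",
            res_name="ALA",
            kind="amino_acid",
        )
        for name in ("N", "CA", "C", "O"):
            res.atoms.append(Atom(name=name, element=name[0], pos=atoms[name]))
        out.append(res)
    for r in out:
        for a in r.atoms:
            a.pos = a.pos + offset_vec
    return out


def build_secstruct_peptide(
    segments: list[tuple[str, int]], chain_id: str = "P", offset=None
) -> list[Residue]:
    """Concatenated ideal-geometry segments, each its own spatial unit."""
    residues: list[Residue] = []
    seq = 1
    shift = np.zeros(3) if offset is None else np.asarray(offset, dtype=float)
    for k, (kind, length) in enumerate(segments):
        local_offset = shift + np.array([0.0, 0.0, 40.0 * k])
        if kind == "helix":
            seg = build_helix(length, chain_id=chain_id, start_seq=seq, offset=local_offset)
        elif kind == "strand":
            seg = build_sheet(length, chain_id=chain_id, start_seq=seq, offset=local_offset)
        elif kind == "coil":
            seg = build_peptide([PHI_PSI["coil"]] * length, chain_id=chain_id, start_seq=seq, offset=local_offset)
        else:
            raise ValueError(f"unknown segment type {kind}")
        seq = seg[-1].seq_num + 5
        residues.extend(seg)
    return residues


def planted_state3_labels(segments: list[tuple[str, int]]) -> list[str]:
    labels = []
    for kind, length in segments:
        n = 2 * length if kind == "strand" else length
        labels.extend([kind] * n)
    return labels
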