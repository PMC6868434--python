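"""Protein-DNA hydrogen-bond detection.

Two interchangeable detectors over the same donor/acceptor chemistry:

* ``detect_hbonds_geometric`` -- distance/angle criteria in the style of
  HBPLUS (donor-acceptor <= 3.9 A, hydrogen-acceptor <= 2.5 A, D-H-A and
  H-A-antecedent angles >= 90 deg by default);
* ``detect_hbonds_energy`` -- the Mayo 12-10 hydrogen-bond potential with
  hybridization-dependent angular factors, accepting bonds at or below an
  energy cutoff (-0.6 kcal/mol by default, the cutoff recommended for
  rigidity analysis with this potential).

X-ray structures rarely include hydrogens, so polar hydrogens are placed at
ideal geometry first: fixed sp2 donors from in-plane 120-degree positions,
rotatable hydroxyls/ammoniums oriented toward the nearest acceptor.

Every reported bond has exactly one protein atom and one DNA atom and is
classified by interaction class (sidechain-base, sidechain-backbone,
mainchain-base, mainchain-backbone) and groove label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from ._geometry import angle_deg, distance, rotate_about, unit
from .dna_model import groove_of_atom
from .structure_io import (
    AnalysisUnit,
    Atom,
    Residue,
    is_dna_backbone_atom,
    is_protein_sidechain_atom,
)

logger = logging.getLogger(__name__)

NH_LENGTH = 1.00
OH_LENGTH = 0.96

# ---------------------------------------------------------------------------
# donor / acceptor chemistry
# ---------------------------------------------------------------------------
# donor spec: atom -> (n_hydrogens, hybridization, placement rule, rule atoms)
# placement rules:
#   amide2   -- two in-plane H at +-120 deg from the N->antecedent bond
#   bisector -- one H opposite the bisector of two bonded neighbours
#   rot1     -- one rotatable H (hydroxyl)
#   rot3     -- three rotatable H (ammonium)
#   peptide  -- backbone amide H (needs previous residue's C)

PROTEIN_DONORS: dict[str, dict[str, tuple[int, str, str, tuple[str, ...]]]] = {
    "*": {"N": (1, "sp2", "peptide", ("CA",))},
    "ARG": {
        "NE": (1, "sp2", "bisector", ("CD", "CZ")),
        "NH1": (2, "sp2", "amide2", ("CZ",)),
        "NH2": (2, "sp2", "amide2", ("CZ",)),
    },
    "LYS": {"NZ": (3, "sp3", "rot3", ("CE",))},
    "HIS": {
        "ND1": (1, "sp2", "bisector", ("CG", "CE1")),
        "NE2": (1, "sp2", "bisector", ("CD2", "CE1")),
    },
    "ASN": {"ND2": (2, "sp2", "amide2", ("CG",))},
    "GLN": {"NE2": (2, "sp2", "amide2", ("CD",))},
    "SER": {"OG": (1, "sp3", "rot1", ("CB",))},
    "THR": {"OG1": (1, "sp3", "rot1", ("CB",))},
    "TYR": {"OH": (1, "sp2", "rot1", ("CZ",))},
    "TRP": {"NE1": (1, "sp2", "bisector", ("CD1", "CE2"))},
}

DNA_DONORS: dict[str, dict[str, tuple[int, str, str, tuple[str, ...]]]] = {
    "DA": {"N6": (2, "sp2", "amide2", ("C6",))},
    "DC": {"N4": (2, "sp2", "amide2", ("C4",))},
    "DG": {
        "N1": (1, "sp2", "bisector", ("C2", "C6")),
        "N2": (2, "sp2", "amide2", ("C2",)),
    },
    "DT": {"N3": (1, "sp2", "bisector", ("C2", "C4"))},
}

# acceptor spec: atom -> (hybridization, antecedent atom)
PROTEIN_ACCEPTORS: dict[str, dict[str, tuple[str, str]]] = {
    "*": {"O": ("sp2", "C"), "OXT": ("sp2", "C")},
    "ASP": {"OD1": ("sp2", "CG"), "OD2": ("sp2", "CG")},
    "GLU": {"OE1": ("sp2", "CD"), "OE2": ("sp2", "CD")},
    "ASN": {"OD1": ("sp2", "CG")},
    "GLN": {"OE1": ("sp2", "CD")},
    "HIS": {"ND1": ("sp2", "CG"), "NE2": ("sp2", "CE1")},
    "SER": {"OG": ("sp3", "CB")},
    "THR": {"OG1": ("sp3", "CB")},
    "TYR": {"OH": ("sp2", "CZ")},
}

DNA_ACCEPTORS: dict[str, dict[str, tuple[str, str]]] = {
    "DA": {"N1": ("sp2", "C2"), "N3": ("sp2", "C2"), "N7": ("sp2", "C5")},
    "DC": {"O2": ("sp2", "C2"), "N3": ("sp2", "C2")},
    "DG": {"O6": ("sp2", "C6"), "N3": ("sp2", "C2"), "N7": ("sp2", "C5")},
    "DT": {"O2": ("sp2", "C2"), "O4": ("sp2", "C4")},
}
# sugar/phosphate acceptors, shared by the four bases
DNA_BACKBONE_ACCEPTORS: dict[str, tuple[str, str]] = {
    "OP1": ("sp3", "P"),
    "OP2": ("sp3", "P"),
    "O1P": ("sp3", "P"),
    "O2P": ("sp3", "P"),
    "O3'": ("sp3", "C3'"),
    "O5'": ("sp3", "C5'"),
    "O4'": ("sp3", "C1'"),
}

#: His nitrogens act as both donor and acceptor (protonation unresolved in
#: X-ray data); at most one bond per His nitrogen and partner atom is kept.
HIS_AMBIGUOUS = {("HIS", "ND1"), ("HIS", "NE2")}


@dataclass
class DetectorParams:
    method: str = "geometric"  # geometric | energy
    max_da: float = 3.9
    max_ha: float = 2.5
    min_dha_deg: float = 90.0
    min_haaa_deg: float = 90.0
    energy_cutoff: float = -0.6
    v0: float = 8.0
    d0: float = 2.8
    energy_prescreen_da: float = 4.5

    def __post_init__(self) -> None:
        if self.method not in ("geometric", "energy"):
            raise ValueError(f"unknown detector method {self.method!r}")
        if self.energy_cutoff >= 0:
            raise ValueError("energy cutoff must be negative")
        if min(self.max_da, self.max_ha, self.d0) <= 0:
            raise ValueError("distance parameters must be positive")


@dataclass
class DonorSite:
    residue: Residue
    atom: Atom
    hybridization: str
    h_positions: list[np.ndarray]
    molecule: str  # protein | dna


@dataclass
class AcceptorSite:
    residue: Residue
    atom: Atom
    hybridization: str
    antecedent: Optional[Atom]
    molecule: str


@dataclass
class HydrogenBond:
    donor_res: Residue
    donor_atom: Atom
    acceptor_res: Residue
    acceptor_atom: Atom
    h_pos: Optional[np.ndarray]
    d_da: float
    d_ha: Optional[float]
    theta_dha: Optional[float]
    energy: Optional[float]
    interaction_class: str = ""
    groove: str = "none"
    dna_chain_id: str = ""

    @property
    def protein_res(self) -> Residue:
        return self.donor_res if self.donor_res.kind == "amino_acid" else self.acceptor_res

    @property
    def protein_atom(self) -> Atom:
        return self.donor_atom if self.donor_res.kind == "amino_acid" else self.acceptor_atom

    @property
    def dna_res(self) -> Residue:
        return self.donor_res if self.donor_res.kind == "nucleotide" else self.acceptor_res

    @property
    def dna_atom(self) -> Atom:
        return self.donor_atom if self.donor_res.kind == "nucleotide" else self.acceptor_atom

    @property
    def is_sidechain_base(self) -> bool:
        return self.interaction_class == "sidechain-base"


# ---------------------------------------------------------------------------
# hydrogen placement
# ---------------------------------------------------------------------------

def _plane_normal(center: np.ndarray, a1: np.ndarray, a2: np.ndarray) -> np.ndarray:
    n = np.cross(a1 - center, a2 - center)
    if np.linalg.norm(n) < 1e-6:
        from ._geometry import perpendicular

        return perpendicular(a1 - center)
    return unit(n)


def _amide2_hydrogens(n_pos, antecedent_pos, plane_ref_pos, length=NH_LENGTH):
    """Two in-plane hydrogens at 120 deg from the N->antecedent bond."""
    u = unit(n_pos - antecedent_pos)
    normal = _plane_normal(antecedent_pos, n_pos, plane_ref_pos)
    h1 = n_pos + length * rotate_about(u, normal, 120.0)
    h2 = n_pos + length * rotate_about(u, normal, -120.0)
    return [h1, h2]


def _bisector_hydrogen(n_pos, nb1_pos, nb2_pos, length=NH_LENGTH):
    d = unit(nb1_pos - n_pos) + unit(nb2_pos - n_pos)
    return [n_pos - length * unit(d)]


def _rotatable_hydrogens(
    o_pos, antecedent_pos, n_h: int, acceptors: list[np.ndarray], length: float
):
    """Orient toward the nearest acceptor within 3.9 A, else staggered."""
    b = unit(o_pos - antecedent_pos)
    best = None
    best_d = 3.9
    for a in acceptors:
        d = distance(o_pos, a)
        if 0.1 < d < best_d:
            best_d, best = d, a
    if best is not None:
        aim = unit(best - o_pos)
        if n_h == 1:
            return [o_pos + length * aim]
        # ammonium: tetrahedral triplet about the bond axis, rotated so one
        # hydrogen comes as close as possible to the aim direction
        perp = aim - np.dot(aim, b) * b
        if np.linalg.norm(perp) < 1e-6:
            from ._geometry import perpendicular

            perp = perpendicular(b)
        p = unit(perp)
        h0 = np.cos(np.radians(70.5)) * b + np.sin(np.radians(70.5)) * p
        return [o_pos + length * rotate_about(h0, b, k * 120.0) for k in range(3)]
    # staggered default, deterministic
    from ._geometry import perpendicular

    p = perpendicular(b)
    h0 = np.cos(np.radians(70.5)) * b + np.sin(np.radians(70.5)) * p
    if n_h == 1:
        return [o_pos + length * h0]
    return [o_pos + length * rotate_about(h0, b, k * 120.0) for k in range(3)]


def _donor_table_for(residue: Residue) -> dict[str, tuple[int, str, str, tuple[str, ...]]]:
    table: dict[str, tuple[int, str, str, tuple[str, ...]]] = {}
    if residue.kind == "amino_acid":
        table.update(PROTEIN_DONORS["*"])
        table.update(PROTEIN_DONORS.get(residue.res_name, {}))
    elif residue.kind == "nucleotide" and residue.base_name:
        table.update(DNA_DONORS.get(residue.base_name, {}))
    return table


def _acceptor_table_for(residue: Residue) -> dict[str, tuple[str, str]]:
    table: dict[str, tuple[str, str]] = {}
    if residue.kind == "amino_acid":
        table.update(PROTEIN_ACCEPTORS["*"])
        table.update(PROTEIN_ACCEPTORS.get(residue.res_name, {}))
    elif residue.kind == "nucleotide" and residue.base_name:
        table.update(DNA_ACCEPTORS.get(residue.base_name, {}))
        table.update(DNA_BACKBONE_ACCEPTORS)
    return table


def enumerate_acceptors(residues: Iterable[Residue], molecule: str) -> list[AcceptorSite]:
    sites = []
    for res in residues:
        table = _acceptor_table_for(res)
        for atom in res.atoms:
            spec = table.get(atom.name)
            if spec is None:
                continue
            hyb, ante_name = spec
            sites.append(
                AcceptorSite(
                    residue=res,
                    atom=atom,
                    hybridization=hyb,
                    antecedent=res.atom(ante_name),
                    molecule=molecule,
                )
            )
    return sites


def place_polar_hydrogens(
    residues: list[Residue],
    molecule: str,
    acceptor_positions: Optional[list[np.ndarray]] = None,
    prev_c_lookup: Optional[dict[tuple, Atom]] = None,
) -> list[DonorSite]:
    """Enumerate donors and place their hydrogens at ideal geometry.

    ``acceptor_positions`` steers rotatable hydroxyls/ammoniums; pass the
    positions of all acceptor atoms of the complex (both molecules).
    Donors whose antecedent atoms are missing are skipped with a warning.
    """
    acceptor_positions = acceptor_positions or []
    sites: list[DonorSite] = []
    for i, res in enumerate(residues):
        table = _donor_table_for(res)
        for atom in res.atoms:
            spec = table.get(atom.name)
            if spec is None:
                continue
            n_h, hyb, rule, rule_atoms = spec
            try:
                if rule == "peptide":
                    prev_c = None
                    if prev_c_lookup is not None:
                        prev_c = prev_c_lookup.get(res.key)
                    elif i > 0 and residues[i - 1].chain_id == res.chain_id:
                        prev_c = residues[i - 1].atom("C")
                    ca = res.atom(rule_atoms[0])
                    if prev_c is None or ca is None or res.res_name == "PRO":
                        raise KeyError("no preceding C / proline")
                    if distance(prev_c.pos, atom.pos) > 2.5:  # chain break
                        raise KeyError("chain break before residue")
                    hs = _bisector_hydrogen(atom.pos, prev_c.pos, ca.pos)
                elif rule == "amide2":
                    ante = res.atom(rule_atoms[0])
                    if ante is None:
                        raise KeyError(rule_atoms[0])
                    # any second substituent of the antecedent fixes the plane
                    ref = next(
                        (
                            a
                            for a in res.atoms
                            if a.name not in (atom.name, ante.name)
                            and distance(a.pos, ante.pos) < 1.6
                        ),
                        None,
                    )
                    if ref is None:
                        raise KeyError(f"plane reference for {atom.name}")
                    hs = _amide2_hydrogens(atom.pos, ante.pos, ref.pos)
                elif rule == "bisector":
                    nb1 = res.atom(rule_atoms[0])
                    nb2 = res.atom(rule_atoms[1])
                    if nb1 is None or nb2 is None:
                        raise KeyError(rule_atoms)
                    hs = _bisector_hydrogen(atom.pos, nb1.pos, nb2.pos)
                elif rule in ("rot1", "rot3"):
                    ante = res.atom(rule_atoms[0])
                    if ante is None:
                        raise KeyError(rule_atoms[0])
                    length = OH_LENGTH if atom.element == "O" else NH_LENGTH
                    hs = _rotatable_hydrogens(
                        atom.pos, ante.pos, n_h, acceptor_positions, length
                    )
                else:  # pragma: no cover
                    raise KeyError(rule)
            except KeyError as exc:
                logger.warning(
                    "donor %s %s skipped: missing antecedent (%s)",
                    res.label(), atom.name, exc,
                )
                continue
            sites.append(
                DonorSite(
                    residue=res,
                    atom=atom,
                    hybridization=hyb,
                    h_positions=[np.asarray(h) for h in hs],
                    molecule=molecule,
                )
            )
    return sites


# ---------------------------------------------------------------------------
# the two detectors
# ---------------------------------------------------------------------------

def prepare_sites(unit_: AnalysisUnit):
    """Donor and acceptor site lists for both molecules of an analysis unit."""
    prot = unit_.protein_residues
    dna = unit_.dna_residues
    prot_acc = enumerate_acceptors(prot, "protein")
    dna_acc = enumerate_acceptors(dna, "dna")
    all_acc_pos = [s.atom.pos for s in prot_acc + dna_acc]
    prot_don = place_polar_hydrogens(prot, "protein", all_acc_pos)
    dna_don = place_polar_hydrogens(dna, "dna", all_acc_pos)
    return prot_don, dna_don, prot_acc, dna_acc


def classify_hbond(hb: HydrogenBond) -> HydrogenBond:
    """Fill interaction class and groove from the atom identities."""
    prot_part = "sidechain" if is_protein_sidechain_atom(hb.protein_atom.name) else "mainchain"
    dna_atom = hb.dna_atom
    dna_res = hb.dna_res
    if is_dna_backbone_atom(dna_atom.name):
        dna_part = "backbone"
        groove = "none"
    else:
        dna_part = "base"
        base = dna_res.base_name
        groove = groove_of_atom(base, dna_atom.name) if base else "none"
    hb.interaction_class = f"{prot_part}-{dna_part}"
    hb.groove = groove
    hb.dna_chain_id = dna_res.chain_id
    return hb


def _pair_key(hb: HydrogenBond):
    return (hb.donor_res.key, hb.donor_atom.name, hb.acceptor_res.key, hb.acceptor_atom.name)


def _dedupe_his(bonds: list[HydrogenBond]) -> list[HydrogenBond]:
    """His N may appear as donor and acceptor toward the same partner; keep
    the better-scoring interpretation only."""
    seen: dict[tuple, HydrogenBond] = {}
    out = []
    for hb in bonds:
        his_atoms = []
        for res, atom in ((hb.donor_res, hb.donor_atom), (hb.acceptor_res, hb.acceptor_atom)):
            if (res.res_name, atom.name) in HIS_AMBIGUOUS:
                his_atoms.append((res.key, atom.name))
        if not his_atoms:
            out.append(hb)
            continue
        partner = (
            (hb.acceptor_res.key, hb.acceptor_atom.name)
            if (hb.donor_res.res_name, hb.donor_atom.name) in HIS_AMBIGUOUS
            else (hb.donor_res.key, hb.donor_atom.name)
        )
        key = (his_atoms[0], partner)
        prev = seen.get(key)
        score = hb.energy if hb.energy is not None else hb.d_da
        prev_score = None if prev is None else (prev.energy if prev.energy is not None else prev.d_da)
        if prev is None or score < prev_score:
            seen[key] = hb
    return out + list(seen.values())


def detect_hbonds_geometric(
    unit_: AnalysisUnit, params: DetectorParams | None = None
) -> list[HydrogenBond]:
    """HBPLUS-style geometric hydrogen-bond detection across the
    protein-DNA interface."""
    params = params or DetectorParams(method="geometric")
    prot_don, dna_don, prot_acc, dna_acc = prepare_sites(unit_)
    bonds: list[HydrogenBond] = []
    for donors, acceptors in ((prot_don, dna_acc), (dna_don, prot_acc)):
        for ds in donors:
            for as_ in acceptors:
                d_da = distance(ds.atom.pos, as_.atom.pos)
                if d_da > params.max_da or d_da < 0.5:
                    continue
                best = None
                for h in ds.h_positions:
                    d_ha = distance(h, as_.atom.pos)
                    if d_ha > params.max_ha:
                        continue
                    theta = angle_deg(ds.atom.pos, h, as_.atom.pos)
                    if theta < params.min_dha_deg:
                        continue
                    if as_.antecedent is not None:
                        phi = angle_deg(h, as_.atom.pos, as_.antecedent.pos)
                        if phi < params.min_haaa_deg:
                            continue
                    if best is None or d_ha < best[0]:
                        best = (d_ha, h, theta)
                if best is None:
                    continue
                d_ha, h, theta = best
                hb = HydrogenBond(
                    donor_res=ds.residue,
                    donor_atom=ds.atom,
                    acceptor_res=as_.residue,
                    acceptor_atom=as_.atom,
                    h_pos=h,
                    d_da=d_da,
                    d_ha=d_ha,
                    theta_dha=theta,
                    energy=None,
                )
                bonds.append(classify_hbond(hb))
    return sorted(_dedupe_his(bonds), key=_pair_key)


def mayo_well(d_da: float, params: DetectorParams) -> float:
    """Radial part of the 12-10 potential, kcal/mol at angular factor 1."""
    r = params.d0 / d_da
    return params.v0 * (5.0 * r**12 - 6.0 * r**10)


def mayo_energy(d_da: float, angular_factor: float, params: DetectorParams | None = None) -> float:
    """Mayo 12-10 hydrogen-bond energy: V0 {5 (d0/d)^12 - 6 (d0/d)^10} F.

    The well bottom sits at d = d0 (2.8 A) with depth -V0 (-8 kcal/mol);
    ``angular_factor`` in [0, 1] carries the hybridization-dependent
    directionality.
    """
    if d_da <= 0:
        raise ValueError("donor-acceptor distance must be positive")
    params = params or DetectorParams(method="energy")
    return mayo_well(d_da, params) * angular_factor


def _out_of_plane_deg(vec: np.ndarray, acceptor: AcceptorSite) -> float:
    """Angle between a vector and the acceptor's sp2 plane (0 = in plane)."""
    a = acceptor.atom.pos
    ante = acceptor.antecedent
    if ante is None:
        return 0.0
    ref = next(
        (
            at
            for at in acceptor.residue.atoms
            if at.name not in (acceptor.atom.name, ante.name)
            and distance(at.pos, ante.pos) < 1.8
        ),
        None,
    )
    if ref is None:
        return 0.0
    n = _plane_normal(ante.pos, a, ref.pos)
    s = abs(np.dot(unit(vec), n))
    return float(np.degrees(np.arcsin(np.clip(s, 0.0, 1.0))))


def angular_factor(
    theta_deg: float, phi_deg: Optional[float], gamma_deg: float,
    donor_hyb: str, acceptor_hyb: str,
) -> float:
    """Directionality term of the 12-10 potential by hybridization case.

    theta: D-H-A angle; phi: H-A-antecedent angle; gamma: out-of-plane
    angle of the H->A approach at an sp2 acceptor.
    """
    ct2 = np.cos(np.radians(theta_deg)) ** 2
    if phi_deg is None:
        phi_deg = 180.0
    if donor_hyb == "sp3" and acceptor_hyb == "sp3":
        return float(ct2 * np.cos(np.radians(phi_deg - 109.5)) ** 2)
    if donor_hyb == "sp3" and acceptor_hyb == "sp2":
        return float(ct2 * np.cos(np.radians(phi_deg)) ** 2)
    if donor_hyb == "sp2" and acceptor_hyb == "sp3":
        return float(ct2 * ct2)
    # sp2 donor, sp2 acceptor
    ang = max(phi_deg, gamma_deg)
    return float(ct2 * np.cos(np.radians(ang)) ** 2)


def detect_hbonds_energy(
    unit_: AnalysisUnit, params: DetectorParams | None = None
) -> list[HydrogenBond]:
    """Energy-based detection: candidates pre-screened at D-A <= 4.5 A and
    D-H-A >= 90 deg, kept iff the 12-10 energy is at or below the cutoff."""
    params = params or DetectorParams(method="energy")
    prot_don, dna_don, prot_acc, dna_acc = prepare_sites(unit_)
    bonds: list[HydrogenBond] = []
    for donors, acceptors in ((prot_don, dna_acc), (dna_don, prot_acc)):
        for ds in donors:
            for as_ in acceptors:
                d_da = distance(ds.atom.pos, as_.atom.pos)
                if d_da > params.energy_prescreen_da or d_da < 0.5:
                    continue
                best = None
                for h in ds.h_positions:
                    theta = angle_deg(ds.atom.pos, h, as_.atom.pos)
                    if theta < 90.0:
                        continue
                    phi = None
                    if as_.antecedent is not None:
                        phi = angle_deg(h, as_.atom.pos, as_.antecedent.pos)
                    gamma = (
                        _out_of_plane_deg(as_.atom.pos - h, as_)
                        if as_.hybridization == "sp2"
                        else 0.0
                    )
                    f = angular_factor(theta, phi, gamma, ds.hybridization, as_.hybridization)
                    e = mayo_energy(d_da, f, params)
                    if e > params.energy_cutoff:
                        continue
                    if best is None or e < best[0]:
                        best = (e, h, theta)
                if best is None:
                    continue
                e, h, theta = best
                hb = HydrogenBond(
                    donor_res=ds.residue,
                    donor_atom=ds.atom,
                    acceptor_res=as_.residue,
                    acceptor_atom=as_.atom,
                    h_pos=h,
                    d_da=d_da,
                    d_ha=distance(h, as_.atom.pos),
                    theta_dha=theta,
                    energy=e,
                )
                bonds.append(classify_hbond(hb))
    return sorted(_dedupe_his(bonds), key=_pair_key)


def detect_hbonds(unit_: AnalysisUnit, params: DetectorParams) -> list[HydrogenBond]:
    if params.method == "geometric":
        return detect_hbonds_geometric(unit_, params)
    return detect_hbonds_energy(unit_, params)


def bonds_to_records(bonds: list[HydrogenBond], pdb_id: str, detector: str) -> list[dict]:
    """Flatten bonds for TSV output."""
    recs = []
    for hb in bonds:
        recs.append(
            {
                "pdb_id": pdb_id,
                "detector": detector,
                "donor": f"{hb.donor_res.chain_id}/{hb.donor_res.res_name}{hb.donor_res.seq_num}/{hb.donor_atom.name}",
                "acceptor": f"{hb.acceptor_res.chain_id}/{hb.acceptor_res.res_name}{hb.acceptor_res.seq_num}/{hb.acceptor_atom.name}",
                "d_da": round(hb.d_da, 3),
                "theta_dha": None if hb.theta_dha is None else round(hb.theta_dha, 1),
                "energy": None if hb.energy is None else round(hb.energy, 3),
                "class": hb.interaction_class,
                "groove": hb.groove,
                "dna_chain": hb.dna_chain_id,
            }
        )
    return recs
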