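"""DNA duplex assembly: Watson-Crick base-pair detection and groove-edge
classification of base atoms.

A base pair is accepted when the two bases are identity-complementary
(A-T or G-C), the purine N1 to pyrimidine N3 distance is <= 3.5 A and the
C1'-C1' distance lies in [9.0, 11.5] A -- thresholds that accept canonical
Watson-Crick geometry and reject stacked or bulged arrangements.  Hoogsteen
and mismatch pairs are intentionally not detected.

Groove labels come from the fixed edge-atom table: atoms that can donate or
accept hydrogen bonds into the major or minor groove of B-DNA.  Atoms on the
Watson-Crick edge (e.g. adenine N1) and all sugar/phosphate atoms map to
"none".
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._geometry import distance
from .structure_io import Residue

PURINES = {"DA", "DG"}
PYRIMIDINES = {"DC", "DT"}
COMPLEMENT = {"DA": "DT", "DT": "DA", "DG": "DC", "DC": "DG"}

#: hydrogen-bond-capable groove edge atoms, per base
MAJOR_GROOVE_ATOMS = {
    "DA": {"N6", "N7"},
    "DG": {"O6", "N7"},
    "DC": {"N4"},
    "DT": {"O4"},
}
MINOR_GROOVE_ATOMS = {
    "DA": {"N3"},
    "DG": {"N3", "N2"},
    "DC": {"O2"},
    "DT": {"O2"},
}

N1N3_MAX = 3.5
C1C1_RANGE = (9.0, 11.5)


class DuplexError(ValueError):
    pass


@dataclass
class BasePair:
    res_i: Residue  # strand 1
    res_j: Residue  # strand 2
    pair_type: str  # AT | GC
    n1n3_dist: float
    c1c1_dist: float

    def __repr__(self) -> str:  # pragma: no cover
        return f"<BasePair {self.res_i.label()} . {self.res_j.label()} ({self.pair_type})>"


@dataclass
class Duplex:
    strand1: list[Residue]
    strand2: list[Residue]
    pairs: list[BasePair] = field(default_factory=list)

    def pair_of(self, residue: Residue) -> BasePair | None:
        for p in self.pairs:
            if p.res_i.key == residue.key or p.res_j.key == residue.key:
                return p
        return None

    def strand_of(self, residue: Residue) -> int:
        """1 or 2; raises if the residue is on neither strand."""
        if any(r.key == residue.key for r in self.strand1):
            return 1
        if any(r.key == residue.key for r in self.strand2):
            return 2
        raise DuplexError(f"residue {residue.label()} not on either duplex strand")


def _wc_reference_atoms(res: Residue):
    """(N1-or-N3 Watson-Crick nitrogen, C1') or raises listing what is missing."""
    base = res.base_name
    if base is None:
        raise DuplexError(f"{res.label()}: not a canonical deoxynucleotide")
    wc_name = "N1" if base in PURINES else "N3"
    wc = res.atom(wc_name)
    c1 = res.atom("C1'") or res.atom("C1*")
    return wc, c1


def detect_base_pairs(strand_a: list[Residue], strand_b: list[Residue]) -> Duplex:
    """Pair the bases of two DNA chains by Watson-Crick geometry.

    Conflicts (a base geometrically compatible with several partners) are
    resolved greedily by smallest N1-N3 distance; each base joins at most
    one pair.
    """
    bad = [
        r.label()
        for r in list(strand_a) + list(strand_b)
        if r.base_name is not None and _wc_reference_atoms(r)[1] is None
    ]
    if bad:
        raise DuplexError(f"residues missing C1' atoms: {', '.join(bad)}")

    candidates: list[tuple[float, float, Residue, Residue]] = []
    for ra in strand_a:
        base_a = ra.base_name
        if base_a is None:
            continue
        wc_a, c1_a = _wc_reference_atoms(ra)
        if wc_a is None:
            continue
        for rb in strand_b:
            base_b = rb.base_name
            if base_b is None or COMPLEMENT[base_a] != base_b:
                continue
            wc_b, c1_b = _wc_reference_atoms(rb)
            if wc_b is None:
                continue
            d_n = distance(wc_a.pos, wc_b.pos)
            d_c = distance(c1_a.pos, c1_b.pos)
            if d_n <= N1N3_MAX and C1C1_RANGE[0] <= d_c <= C1C1_RANGE[1]:
                candidates.append((d_n, d_c, ra, rb))

    candidates.sort(key=lambda t: (t[0], t[2].seq_num, t[3].seq_num))
    used_a: set = set()
    used_b: set = set()
    pairs: list[BasePair] = []
    for d_n, d_c, ra, rb in candidates:
        if ra.key in used_a or rb.key in used_b:
            continue
        used_a.add(ra.key)
        used_b.add(rb.key)
        pair_type = "GC" if ra.base_name in ("DG", "DC") else "AT"
        pairs.append(BasePair(res_i=ra, res_j=rb, pair_type=pair_type, n1n3_dist=d_n, c1c1_dist=d_c))
    pairs.sort(key=lambda p: [r.key for r in strand_a].index(p.res_i.key) if p.res_i.key in {r.key for r in strand_a} else 0)
    return Duplex(strand1=list(strand_a), strand2=list(strand_b), pairs=pairs)


def groove_of_atom(res_name: str, atom_name: str) -> str:
    """major / minor / none for a DNA atom, from the fixed edge-atom table."""
    if res_name not in COMPLEMENT:
        raise ValueError(f"unknown DNA residue code {res_name!r}")
    if atom_name in MAJOR_GROOVE_ATOMS[res_name]:
        return "major"
    if atom_name in MINOR_GROOVE_ATOMS[res_name]:
        return "minor"
    return "none"
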