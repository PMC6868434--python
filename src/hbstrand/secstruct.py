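"""Kabsch-Sander secondary-structure assignment and 3-state reduction.

Backbone C=O...H-N hydrogen bonds are scored with the classic electrostatic
model

    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)  kcal/mol,

a bond existing when E < -0.5 kcal/mol.  The amide hydrogen is placed 1 A
from N, anti-parallel to the preceding residue's carbonyl.  From the bond
graph the standard 8 states are derived (n-turns at offsets 3/4/5 giving
G/H/I helices, bridge pairs giving B and ladders E, turns T and bends S),
then reduced to the 3 types used throughout the analysis:

    helix = {H, G, I};  strand = {E, B};  coil = everything else.

Overlap priority follows the original assignment order (H, then E/B, then
G, I, T, S); polyproline states from newer assigners are not produced and
would reduce to coil anyway.  A reader for classic DSSP output files allows
cross-checking the reduction against an external assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._geometry import angle_deg, distance, unit
from .structure_io import Residue

KS_COUPLING = 0.084 * 332  # kcal/mol * A
KS_BOND_CUTOFF = -0.5
KS_MIN_ENERGY = -9.9
CHAIN_BREAK_CA = 4.5

STATE3_OF = {
    "H": "helix", "G": "helix", "I": "helix",
    "E": "strand", "B": "strand",
    "T": "coil", "S": "coil", "-": "coil", "P": "coil", " ": "coil",
}


def reduce_state(state8: str) -> str:
    """Total 3-state reduction; unknown symbols count as coil."""
    return STATE3_OF.get(state8, "coil")


@dataclass
class SecStructAssignment:
    residues: list[Residue]
    state8: list[str]
    state3: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.state3:
            self.state3 = [reduce_state(s) for s in self.state8]

    def state3_of(self, residue: Residue) -> str:
        for r, s in zip(self.residues, self.state3):
            if r.key == residue.key:
                return s
        raise KeyError(f"residue {residue.label()} not in assignment")


def ks_energy_from_distances(r_on: float, r_ch: float, r_oh: float, r_cn: float) -> float:
    """The energy as a function of the four interatomic distances (A)."""
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:
        return KS_MIN_ENERGY
    e = KS_COUPLING * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
    return max(e, KS_MIN_ENERGY)


def ks_energy(
    c_pos: np.ndarray, o_pos: np.ndarray, n_pos: np.ndarray, h_pos: np.ndarray
) -> float:
    """Electrostatic C=O...H-N hydrogen-bond energy, kcal/mol."""
    return ks_energy_from_distances(
        distance(o_pos, n_pos),
        distance(c_pos, h_pos),
        distance(o_pos, h_pos),
        distance(c_pos, n_pos),
    )


def _backbone(res: Residue):
    return tuple(res.atom(name) for name in ("N", "CA", "C", "O"))


def _hbond_matrix(residues: list[Residue]) -> tuple[np.ndarray, list[bool]]:
    """bond[i, j]: CO of residue i donates to NH of residue j (E < -0.5)."""
    n = len(residues)
    backbone = [_backbone(r) for r in residues]
    # amide H: 1 A from N, anti-parallel to the previous carbonyl
    h_pos: list = [None] * n
    breaks = [False] * n  # break BEFORE residue i
    for i, res in enumerate(residues):
        n_at, ca, c, o = backbone[i]
        if i == 0:
            breaks[i] = True
        else:
            prev_ca = backbone[i - 1][1]
            if ca is None or prev_ca is None or distance(ca.pos, prev_ca.pos) > CHAIN_BREAK_CA:
                breaks[i] = True
        if res.res_name == "PRO" or n_at is None or breaks[i]:
            continue
        prev_c, prev_o = backbone[i - 1][2], backbone[i - 1][3]
        if prev_c is None or prev_o is None:
            continue
        h_pos[i] = n_at.pos + unit(prev_c.pos - prev_o.pos)
    bond = np.zeros((n, n), dtype=bool)
    for i in range(n):
        c, o = backbone[i][2], backbone[i][3]
        if c is None or o is None:
            continue
        for j in range(n):
            if abs(i - j) < 2 or h_pos[j] is None:
                continue
            n_at = backbone[j][0]
            if distance(c.pos, n_at.pos) > 7.0:  # beyond any plausible bond
                continue
            if ks_energy(c.pos, o.pos, n_at.pos, h_pos[j]) < KS_BOND_CUTOFF:
                bond[i, j] = True
    return bond, breaks


def _contiguous(breaks: list[bool], i: int, j: int) -> bool:
    return not any(breaks[k] for k in range(i + 1, j + 1))


def assign_secstruct(residues: list[Residue]) -> SecStructAssignment:
    """8-state Kabsch-Sander assignment for one protein chain (or a chain
    with breaks), reduced to helix/strand/coil."""
    residues = [r for r in residues if r.kind == "amino_acid"]
    n = len(residues)
    if n < 3:
        return SecStructAssignment(residues=residues, state8=["-"] * n)
    bond, breaks = _hbond_matrix(residues)

    turn = {k: [False] * n for k in (3, 4, 5)}
    for k in (3, 4, 5):
        for i in range(n - k):
            if bond[i, i + k] and _contiguous(breaks, i, i + k):
                turn[k][i] = True

    state = ["-"] * n

    def mark(i, sym):
        if state[i] == "-" or (sym == "H" and state[i] in "GIT") :
            state[i] = sym

    # bridges and ladders
    partner_type = [None] * n
    bridges = []
    for i in range(1, n - 1):
        for j in range(i + 3, n - 1):
            para = (bond[i - 1, j] and bond[j, i + 1]) or (bond[j - 1, i] and bond[i, j + 1])
            anti = (bond[i, j] and bond[j, i]) or (bond[i - 1, j + 1] and bond[j - 1, i + 1])
            if para or anti:
                bridges.append((i, j, "P" if para else "A"))
    in_ladder = set()
    bridge_set = {(i, j, t) for i, j, t in bridges}
    for i, j, t in bridges:
        ext = (
            (i + 1, j + 1, "P") in bridge_set
            or (i - 1, j - 1, "P") in bridge_set
            if t == "P"
            else (i + 1, j - 1, "A") in bridge_set or (i - 1, j + 1, "A") in bridge_set
        )
        if ext:
            in_ladder.update((i, j))

    # 4-helix first (highest priority), then strands, then 3/5 helices
    helix4 = [False] * n
    for i in range(1, n - 4):
        if turn[4][i - 1] and turn[4][i]:
            for k in range(i, i + 4):
                helix4[k] = True
    for i, flag in enumerate(helix4):
        if flag:
            state[i] = "H"
    for i, j, t in bridges:
        for k in (i, j):
            if state[k] == "-":
                state[k] = "E" if k in in_ladder else "B"
    for koff, sym in ((3, "G"), (5, "I")):
        for i in range(1, n - koff):
            if turn[koff][i - 1] and turn[koff][i]:
                for k in range(i, i + koff):
                    if state[k] == "-":
                        state[k] = sym
    # turns
    for k in (3, 4, 5):
        for i in range(n):
            if turn[k][i]:
                for m in range(i + 1, min(i + k, n)):
                    if state[m] == "-":
                        state[m] = "T"
    # bends
    for i in range(2, n - 2):
        if state[i] != "-":
            continue
        cas = [residues[i + d].atom("CA") for d in (-2, 0, 2)]
        if any(a is None for a in cas):
            continue
        if not (_contiguous(breaks, i - 2, i) and _contiguous(breaks, i, i + 2)):
            continue
        kink = angle_deg(cas[0].pos, cas[1].pos, cas[2].pos)
        if 180.0 - kink > 70.0:
            state[i] = "S"
    return SecStructAssignment(residues=residues, state8=state)


# ---------------------------------------------------------------------------
# classic DSSP output reader (for external cross-checks)
# ---------------------------------------------------------------------------

def read_dssp(path: str) -> list[tuple[str, int, str, str]]:
    """Parse a classic .dssp file into (chain, seq_num, state8, state3)."""
    rows = []
    with open(path) as fh:
        in_table = False
        for line in fh:
            if line.startswith("  #  RESIDUE"):
                in_table = True
                continue
            if not in_table or len(line) < 17:
                continue
            if line[13] == "!":  # chain break record
                continue
            chain = line[11].strip()
            try:
                seq_num = int(line[5:10])
            except ValueError:
                continue
            state8 = line[16] if line[16] != " " else "-"
            rows.append((chain, seq_num, state8, reduce_state(state8)))
    return rows
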