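"""Coordinate I/O, chain classification and manifest handling.

Parses PDB/mmCIF files (via gemmi) into a light Chain -> Residue -> Atom
hierarchy that the rest of the pipeline operates on.  Author chain ids and
residue numbering are preserved; alternate conformations are collapsed to
the highest-occupancy conformer; input hydrogens are discarded (the
hydrogen-bond detectors re-place polar hydrogens at ideal geometry so that
structures solved with and without hydrogens are treated uniformly).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import gemmi
import numpy as np

AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "SEC", "PYL",
}
DEOXYNUCLEOTIDES = {"DA", "DC", "DG", "DT"}

#: modified deoxynucleotides mapped to their parent canonical base; residues
#: not listed here and not canonical are excluded from base-level analysis
MODIFIED_BASE_PARENTS = {
    "5CM": "DC",  # 5-methylcytosine
    "5MC": "DC",
    "6OG": "DG",
    "8OG": "DG",  # 8-oxoguanine
    "BRU": "DT",  # 5-bromo-dU pairs as T
    "5IU": "DT",
    "DU": "DT",
}

BACKBONE_PROTEIN_ATOMS = {"N", "CA", "C", "O", "OXT"}
#: DNA sugar/phosphate atom names (PDB v3); everything else in a nucleotide
#: is a base atom
DNA_BACKBONE_ATOMS = {
    "P", "OP1", "OP2", "OP3", "O1P", "O2P", "O3P",
    "O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'", "O2'", "C1'",
    "O5*", "C5*", "C4*", "O4*", "C3*", "O3*", "C2*", "C1*",
}


class StructureParseError(ValueError):
    pass


class SelectionError(ValueError):
    pass


@dataclass
class Atom:
    name: str
    element: str
    pos: np.ndarray
    altloc: str = ""
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float)
        if not np.all(np.isfinite(self.pos)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")


@dataclass
class Residue:
    chain_id: str
    seq_num: int
    icode: str
    res_name: str
    kind: str  # amino_acid | nucleotide | other
    atoms: list[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_num, self.icode)

    @property
    def base_name(self) -> Optional[str]:
        """Canonical DA/DC/DG/DT code, mapping modified bases to parents."""
        if self.res_name in DEOXYNUCLEOTIDES:
            return self.res_name
        return MODIFIED_BASE_PARENTS.get(self.res_name)

    def label(self) -> str:
        # e.g. "DC-9 (chain E)" / "ARG-191 (chain A)"
        return f"{self.res_name}-{self.seq_num}{self.icode.strip()} (chain {self.chain_id})"

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Residue {self.res_name} {self.chain_id}{self.seq_num}{self.icode}>"


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)


@dataclass
class Structure:
    name: str
    chains: list[Chain] = field(default_factory=list)

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise SelectionError(f"chain {chain_id!r} not found in {self.name}")

    def has_chain(self, chain_id: str) -> bool:
        return any(c.chain_id == chain_id for c in self.chains)


@dataclass
class ChainRole:
    chain_id: str
    role: str  # protein | dna | other


@dataclass
class ManifestEntry:
    pdb_id: str
    group: str  # HS | MS | NS
    protein_chain: str
    residue_range: Optional[tuple[int, int]]  # inclusive, author numbering
    dna_chain_ids: tuple[str, str]
    scope: str  # domain | chain

    @property
    def scope_effective(self) -> str:
        return "domain" if self.residue_range is not None and self.scope == "domain" else self.scope


@dataclass
class AnalysisUnit:
    """A protein residue selection paired with the two DNA chains."""

    structure: Structure
    entry: ManifestEntry
    protein_residues: list[Residue]
    dna_strand1: list[Residue]
    dna_strand2: list[Residue]

    @property
    def dna_residues(self) -> list[Residue]:
        return list(self.dna_strand1) + list(self.dna_strand2)


def residue_kind(res_name: str) -> str:
    name = res_name.strip().upper()
    if name in AMINO_ACIDS:
        return "amino_acid"
    if name in DEOXYNUCLEOTIDES or name in MODIFIED_BASE_PARENTS:
        return "nucleotide"
    return "other"


def _best_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins; ties broken by altloc identifier, alphabetical
    return sorted(atoms, key=lambda a: (-a.occ, a.altloc))[0]


def parse_structure(path: str | os.PathLike, fmt: str = "auto") -> Structure:
    """Read a PDB or mmCIF file into the package hierarchy.

    Only the first model is used.  Waters and ligands are retained with
    kind="other"; hydrogens are dropped; for each altloc group only the
    highest-occupancy conformer is kept (ties: first alphabetically).
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise StructureParseError(f"file not found: {path}")
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(path)
        elif fmt in ("mmcif", "cif"):
            st = gemmi.make_structure_from_block(gemmi.cif.read(path)[0])
        elif fmt == "auto":
            st = gemmi.read_structure(path)
        else:
            raise StructureParseError(f"unknown format {fmt!r}")
    except (RuntimeError, ValueError, IndexError) as exc:
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureParseError(f"{path}: no models")
    model = st[0]
    out = Structure(name=st.name.lower() or os.path.basename(path))
    for ch in model:
        chain = Chain(chain_id=ch.name)
        for res in ch:
            kind = residue_kind(res.name)
            r = Residue(
                chain_id=ch.name,
                seq_num=res.seqid.num,
                icode=(res.seqid.icode or "").strip(),
                res_name=res.name.strip().upper(),
                kind=kind,
            )
            by_name: dict[str, list[gemmi.Atom]] = {}
            for at in res:
                if at.element.is_hydrogen:
                    continue
                by_name.setdefault(at.name, []).append(at)
            for name, group in by_name.items():
                best = _best_altloc(group)
                r.atoms.append(
                    Atom(
                        name=name,
                        element=best.element.name,
                        pos=np.array([best.pos.x, best.pos.y, best.pos.z]),
                        altloc=best.altloc or "",
                        occupancy=best.occ,
                    )
                )
            if r.atoms:
                chain.residues.append(r)
        if chain.residues:
            out.chains.append(chain)
    if not out.chains:
        raise StructureParseError(f"{path}: empty model")
    return out


def classify_chains(structure: Structure, threshold: float = 0.8) -> list[ChainRole]:
    """Label every chain protein/dna/other by residue-composition majority."""
    roles = []
    for chain in structure.chains:
        polymer = [r for r in chain.residues if r.kind in ("amino_acid", "nucleotide")]
        n = len(polymer)
        role = "other"
        if n > 0:
            frac_aa = sum(r.kind == "amino_acid" for r in polymer) / n
            frac_nt = sum(r.kind == "nucleotide" for r in polymer) / n
            # waters/ligands in a polymer chain do not count against it
            if frac_aa >= threshold and sum(r.kind == "amino_acid" for r in chain.residues) >= 1:
                role = "protein"
            elif frac_nt >= threshold:
                role = "dna"
        roles.append(ChainRole(chain_id=chain.chain_id, role=role))
    return roles


def apply_selector(structure: Structure, entry: ManifestEntry) -> AnalysisUnit:
    """Select the protein residues named by the manifest entry and pair them
    with the two DNA chains.

    scope="chain" keeps the whole protein chain; scope="domain" restricts to
    the inclusive author-numbered residue range.  Residues outside the range
    take no part in any downstream counting.
    """
    chain = structure.chain(entry.protein_chain)
    residues = [r for r in chain.residues if r.kind == "amino_acid"]
    if entry.scope == "domain" and entry.residue_range is not None:
        lo, hi = entry.residue_range
        residues = [r for r in residues if lo <= r.seq_num <= hi]
    if not residues:
        raise SelectionError(
            f"{entry.pdb_id}: empty protein selection for chain "
            f"{entry.protein_chain} range {entry.residue_range}"
        )
    s1 = [r for r in structure.chain(entry.dna_chain_ids[0]).residues if r.kind == "nucleotide"]
    s2 = [r for r in structure.chain(entry.dna_chain_ids[1]).residues if r.kind == "nucleotide"]
    if not s1 or not s2:
        raise SelectionError(f"{entry.pdb_id}: DNA chains {entry.dna_chain_ids} have no nucleotides")
    return AnalysisUnit(
        structure=structure,
        entry=entry,
        protein_residues=residues,
        dna_strand1=s1,
        dna_strand2=s2,
    )


def parse_protein_selector(text: str) -> tuple[str, Optional[tuple[int, int]]]:
    """Parse "A" or "D:3-226" into (chain_id, residue_range)."""
    text = text.strip()
    if ":" not in text:
        return text, None
    chain, rng = text.split(":", 1)
    lo_s, hi_s = rng.split("-", 1)
    lo, hi = int(lo_s), int(hi_s)
    if hi < lo:
        raise ValueError(f"empty residue range in selector {text!r}")
    return chain.strip(), (lo, hi)


def read_manifest(path: str | os.PathLike) -> list[ManifestEntry]:
    """Read the dataset manifest TSV.

    Columns: pdb_id, group, protein_selector, dna_chains, scope.
    """
    entries: list[ManifestEntry] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        required = {"pdb_id", "group", "protein_selector", "dna_chains", "scope"}
        missing = required - set(idx)
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            chain, rng = parse_protein_selector(f[idx["protein_selector"]])
            dna = tuple(c.strip() for c in f[idx["dna_chains"]].split(","))
            if len(dna) != 2:
                raise ValueError(f"{f[idx['pdb_id']]}: need exactly 2 DNA chains, got {dna}")
            group = f[idx["group"]].strip().upper()
            if group not in ("HS", "MS", "NS"):
                raise ValueError(f"unknown specificity group {group!r}")
            entries.append(
                ManifestEntry(
                    pdb_id=f[idx["pdb_id"]].strip().lower(),
                    group=group,
                    protein_chain=chain,
                    residue_range=rng,
                    dna_chain_ids=(dna[0], dna[1]),
                    scope=f[idx["scope"]].strip().lower(),
                )
            )
    return entries


def find_structure_file(directory: str | os.PathLike, pdb_id: str) -> Optional[str]:
    """Locate pdb_id.{pdb,cif,ent} (any case) in a local mirror directory."""
    directory = os.fspath(directory)
    for stem in (pdb_id.lower(), pdb_id.upper()):
        for ext in (".pdb", ".ent", ".cif", ".mmcif"):
            cand = os.path.join(directory, stem + ext)
            if os.path.exists(cand):
                return cand
    return None


def is_dna_backbone_atom(name: str) -> bool:
    return name in DNA_BACKBONE_ATOMS


def is_dna_base_atom(residue: Residue, name: str) -> bool:
    return residue.kind == "nucleotide" and not is_dna_backbone_atom(name)


def is_protein_sidechain_atom(name: str) -> bool:
    return name not in BACKBONE_PROTEIN_ATOMS


def iter_atoms(residues: Iterable[Residue]) -> Iterator[tuple[Residue, Atom]]:
    for r in residues:
        for a in r.atoms:
            yield r, a
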