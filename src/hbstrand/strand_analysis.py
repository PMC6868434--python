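"""Per-strand bookkeeping of side chain-base hydrogen bonds.

For each complex: how many side chain-base hydrogen bonds each DNA strand
receives (overall and split by groove), which strand dominates and by what
percentage, whether the two strands tie (a "50/50 case", either by bond
counts or by engaged-base counts in the major groove), which bases are
engaged, and which Watson-Crick pairs have BOTH bases engaged ("base-pair
side chain-base hydrogen bonds").  Group-level summaries aggregate these
per-complex records within a specificity group (HS/MS/NS).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .dna_model import BasePair, Duplex
from .hbond_detect import HydrogenBond
from .structure_io import ManifestEntry


class SummaryError(ValueError):
    pass


@dataclass
class ComplexSummary:
    pdb_id: str
    group: str
    detector: str
    n_scb_strand1: int = 0
    n_scb_strand2: int = 0
    n_scb_major_s1: int = 0
    n_scb_major_s2: int = 0
    n_scb_minor_s1: int = 0
    n_scb_minor_s2: int = 0
    n_nonscb_s1: int = 0
    n_nonscb_s2: int = 0
    e_scb_s1: Optional[float] = None
    e_scb_s2: Optional[float] = None
    engaged_bases_s1: set = field(default_factory=set)
    engaged_bases_s2: set = field(default_factory=set)
    engaged_bases_major_s1: set = field(default_factory=set)
    engaged_bases_major_s2: set = field(default_factory=set)
    engaged_bases_minor_s1: set = field(default_factory=set)
    engaged_bases_minor_s2: set = field(default_factory=set)
    dominant_strand: Optional[int] = None
    pct_dominant: Optional[float] = None
    is_5050_bonds: bool = False
    is_5050_bases_major: bool = False
    bp_hb: list = field(default_factory=list)
    bp_hb_major: list = field(default_factory=list)
    n_bp_hb_GC: int = 0
    n_bp_hb_AT: int = 0

    @property
    def has_scb(self) -> bool:
        return self.n_scb_strand1 + self.n_scb_strand2 > 0

    @property
    def one_strand_only(self) -> bool:
        return self.has_scb and min(self.n_scb_strand1, self.n_scb_strand2) == 0

    def pct_dominant_for(self, n1: int, n2: int) -> Optional[float]:
        return 100.0 * max(n1, n2) / (n1 + n2) if n1 + n2 > 0 else None

    @property
    def pct_dominant_major(self) -> Optional[float]:
        return self.pct_dominant_for(self.n_scb_major_s1, self.n_scb_major_s2)

    @property
    def pct_dominant_minor(self) -> Optional[float]:
        return self.pct_dominant_for(self.n_scb_minor_s1, self.n_scb_minor_s2)

    @property
    def pct_dominant_nonscb(self) -> Optional[float]:
        return self.pct_dominant_for(self.n_nonscb_s1, self.n_nonscb_s2)

    @property
    def pct_dominant_bases(self) -> Optional[float]:
        return self.pct_dominant_for(len(self.engaged_bases_s1), len(self.engaged_bases_s2))

    @property
    def pct_dominant_bases_major(self) -> Optional[float]:
        return self.pct_dominant_for(
            len(self.engaged_bases_major_s1), len(self.engaged_bases_major_s2)
        )

    @property
    def pct_dominant_bases_minor(self) -> Optional[float]:
        return self.pct_dominant_for(
            len(self.engaged_bases_minor_s1), len(self.engaged_bases_minor_s2)
        )


@dataclass
class GroupSummary:
    group: str
    detector: str
    n_complexes: int = 0
    n_complexes_with_scb: int = 0
    n_equal_contribution: int = 0  # 50/50 by bond counts
    n_dominant_le75: int = 0  # dominant strand contributes <= 75%
    n_one_strand_only: int = 0
    n_5050_bases_major: int = 0  # 50/50 by engaged bases, major groove
    n_5050_with_bp: int = 0  # of those, with >=1 engaged pair (major)
    n_with_ge1_bp: int = 0
    n_with_ge2_bp: int = 0
    n_bp_GC_total: int = 0
    n_bp_AT_total: int = 0
    pct_dominant_sorted: list = field(default_factory=list)  # descending


def _strand_index(hb: HydrogenBond, duplex: Duplex) -> int:
    return duplex.strand_of(hb.dna_res)


def summarize_complex(
    bonds: list[HydrogenBond],
    duplex: Duplex,
    entry: ManifestEntry,
    detector: str = "geometric",
) -> ComplexSummary:
    """Reduce a complex's bond list to its per-strand summary.

    Ties for the dominant strand are broken deterministically toward
    strand 1 and flagged as 50/50; either strand may equally be called
    dominant in that case.
    """
    cs = ComplexSummary(pdb_id=entry.pdb_id, group=entry.group, detector=detector)
    energies = [0.0, 0.0]
    any_energy = False
    for hb in bonds:
        s = _strand_index(hb, duplex)  # raises for foreign residues
        if hb.is_sidechain_base:
            key = hb.dna_res.key
            if s == 1:
                cs.n_scb_strand1 += 1
                cs.engaged_bases_s1.add(key)
            else:
                cs.n_scb_strand2 += 1
                cs.engaged_bases_s2.add(key)
            if hb.groove == "major":
                if s == 1:
                    cs.n_scb_major_s1 += 1
                    cs.engaged_bases_major_s1.add(key)
                else:
                    cs.n_scb_major_s2 += 1
                    cs.engaged_bases_major_s2.add(key)
            elif hb.groove == "minor":
                if s == 1:
                    cs.n_scb_minor_s1 += 1
                    cs.engaged_bases_minor_s1.add(key)
                else:
                    cs.n_scb_minor_s2 += 1
                    cs.engaged_bases_minor_s2.add(key)
            if hb.energy is not None:
                energies[s - 1] += hb.energy
                any_energy = True
        else:
            if s == 1:
                cs.n_nonscb_s1 += 1
            else:
                cs.n_nonscb_s2 += 1
    if any_energy:
        cs.e_scb_s1, cs.e_scb_s2 = energies
    n1, n2 = cs.n_scb_strand1, cs.n_scb_strand2
    if n1 + n2 > 0:
        cs.pct_dominant = 100.0 * max(n1, n2) / (n1 + n2)
        cs.dominant_strand = 1 if n1 >= n2 else 2
        cs.is_5050_bonds = n1 == n2
    m1 = len(cs.engaged_bases_major_s1)
    m2 = len(cs.engaged_bases_major_s2)
    cs.is_5050_bases_major = m1 == m2 and m1 > 0
    cs.bp_hb = find_basepair_hbonds(bonds, duplex, "both")
    cs.bp_hb_major = find_basepair_hbonds(bonds, duplex, "major")
    cs.n_bp_hb_GC = sum(1 for p in cs.bp_hb if p.pair_type == "GC")
    cs.n_bp_hb_AT = sum(1 for p in cs.bp_hb if p.pair_type == "AT")
    return cs


def find_basepair_hbonds(
    bonds: list[HydrogenBond], duplex: Duplex, groove_filter: str = "both"
) -> list[BasePair]:
    """Watson-Crick pairs whose BOTH bases receive at least one side
    chain-base hydrogen bond passing the groove filter."""
    if groove_filter not in ("both", "major", "minor"):
        raise ValueError(f"unknown groove filter {groove_filter!r}")
    grooves = ("major", "minor") if groove_filter == "both" else (groove_filter,)
    engaged: set = set()
    for hb in bonds:
        if hb.is_sidechain_base and hb.groove in grooves:
            engaged.add(hb.dna_res.key)
    return [p for p in duplex.pairs if p.res_i.key in engaged and p.res_j.key in engaged]


def summarize_group(summaries: list[ComplexSummary]) -> GroupSummary:
    """Aggregate per-complex summaries of one specificity group.

    Complexes without any side chain-base hydrogen bond count toward
    ``n_complexes`` but are excluded from every percentage-based statistic.
    """
    if not summaries:
        return GroupSummary(group="", detector="")
    groups = {s.group for s in summaries}
    detectors = {s.detector for s in summaries}
    if len(groups) > 1 or len(detectors) > 1:
        raise SummaryError(f"mixed groups {groups} / detectors {detectors}")
    gs = GroupSummary(group=summaries[0].group, detector=summaries[0].detector)
    gs.n_complexes = len(summaries)
    for cs in summaries:
        if not cs.has_scb:
            continue
        gs.n_complexes_with_scb += 1
        if cs.is_5050_bonds:
            gs.n_equal_contribution += 1
        if cs.pct_dominant is not None and cs.pct_dominant <= 75.0:
            gs.n_dominant_le75 += 1
        if cs.one_strand_only:
            gs.n_one_strand_only += 1
        if cs.is_5050_bases_major:
            gs.n_5050_bases_major += 1
            if cs.bp_hb_major:
                gs.n_5050_with_bp += 1
        if len(cs.bp_hb) >= 1:
            gs.n_with_ge1_bp += 1
        if len(cs.bp_hb) >= 2:
            gs.n_with_ge2_bp += 1
        gs.n_bp_GC_total += cs.n_bp_hb_GC
        gs.n_bp_AT_total += cs.n_bp_hb_AT
    gs.pct_dominant_sorted = sorted(
        (cs.pct_dominant for cs in summaries if cs.pct_dominant is not None), reverse=True
    )
    return gs


def complex_summary_record(cs: ComplexSummary) -> dict:
    """Flatten for the per-complex TSV."""
    return {
        "pdb_id": cs.pdb_id,
        "group": cs.group,
        "detector": cs.detector,
        "n_scb_s1": cs.n_scb_strand1,
        "n_scb_s2": cs.n_scb_strand2,
        "n_scb_major_s1": cs.n_scb_major_s1,
        "n_scb_major_s2": cs.n_scb_major_s2,
        "n_scb_minor_s1": cs.n_scb_minor_s1,
        "n_scb_minor_s2": cs.n_scb_minor_s2,
        "n_nonscb_s1": cs.n_nonscb_s1,
        "n_nonscb_s2": cs.n_nonscb_s2,
        "e_scb_s1": cs.e_scb_s1,
        "e_scb_s2": cs.e_scb_s2,
        "n_engaged_bases_s1": len(cs.engaged_bases_s1),
        "n_engaged_bases_s2": len(cs.engaged_bases_s2),
        "n_engaged_major_s1": len(cs.engaged_bases_major_s1),
        "n_engaged_major_s2": len(cs.engaged_bases_major_s2),
        "dominant_strand": cs.dominant_strand,
        "pct_dominant": None if cs.pct_dominant is None else round(cs.pct_dominant, 2),
        "is_5050_bonds": cs.is_5050_bonds,
        "is_5050_bases_major": cs.is_5050_bases_major,
        "n_bp_hb": len(cs.bp_hb),
        "n_bp_hb_major": len(cs.bp_hb_major),
        "n_bp_hb_GC": cs.n_bp_hb_GC,
        "n_bp_hb_AT": cs.n_bp_hb_AT,
        "has_scb": cs.has_scb,
    }
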