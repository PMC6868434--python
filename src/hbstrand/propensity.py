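"""Secondary-structure propensities of DNA-interacting residues.

A propensity compares the relative frequency of a secondary-structure type
(helix/strand/coil) in a foreground residue set against a background set:

    propensity(s) = [count_fg(s) / |fg|] / [count_bg(s) / |bg|]

Values above 1 mean enrichment of that conformation among, e.g., the DNA
base-contacting residues relative to all residues of the DNA-binding
domains.  Residues occurring in several complexes contribute once per
complex occurrence (pooled counts over a group).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

from ._geometry import distance
from .structure_io import (
    AnalysisUnit,
    Residue,
    is_dna_backbone_atom,
    is_protein_sidechain_atom,
)

STATE3 = ("helix", "strand", "coil")
BASE_CONTACT_CUTOFF = 4.5


@dataclass
class PropensityTable:
    foreground_label: str
    background_label: str
    groove_scope: str = "both"
    counts_fg: dict = field(default_factory=dict)
    counts_bg: dict = field(default_factory=dict)
    propensity: dict = field(default_factory=dict)

    def freq(self, which: str, state: str) -> float:
        counts = self.counts_fg if which == "fg" else self.counts_bg
        total = sum(counts.values())
        return counts.get(state, 0) / total if total else 0.0


def base_contacting_residues(unit: AnalysisUnit, cutoff: float = BASE_CONTACT_CUTOFF) -> list[Residue]:
    """Protein residues with >= 1 side-chain heavy atom within ``cutoff`` of
    any DNA *base* heavy atom (sugar/phosphate contacts do not qualify;
    glycine, whose only side-chain position is CA, never qualifies)."""
    base_atoms = [
        a.pos
        for r in unit.dna_residues
        if r.base_name is not None
        for a in r.atoms
        if not is_dna_backbone_atom(a.name)
    ]
    out = []
    for res in unit.protein_residues:
        side = [a for a in res.atoms if is_protein_sidechain_atom(a.name)]
        hit = any(distance(a.pos, b) <= cutoff for a in side for b in base_atoms)
        if hit:
            out.append(res)
    return out


def compute_propensity(
    fg_states: Iterable[str],
    bg_states: Iterable[str],
    foreground_label: str = "base_contacting",
    background_label: str = "all_domain_residues",
    groove_scope: str = "both",
) -> PropensityTable:
    """Propensity table from foreground/background 3-state label multisets.

    A background type with zero frequency but nonzero foreground frequency
    yields an infinite propensity (flagged as math.inf).
    """
    fg = list(fg_states)
    bg = list(bg_states)
    if not fg or not bg:
        raise ValueError("foreground and background must be non-empty")
    bad = (set(fg) | set(bg)) - set(STATE3)
    if bad:
        raise ValueError(f"unknown 3-state labels: {sorted(bad)}")
    table = PropensityTable(
        foreground_label=foreground_label,
        background_label=background_label,
        groove_scope=groove_scope,
        counts_fg={s: fg.count(s) for s in STATE3},
        counts_bg={s: bg.count(s) for s in STATE3},
    )
    for s in STATE3:
        f_fg = table.counts_fg[s] / len(fg)
        f_bg = table.counts_bg[s] / len(bg)
        if f_bg == 0.0:
            table.propensity[s] = math.inf if f_fg > 0 else 0.0
        else:
            table.propensity[s] = f_fg / f_bg
    return table


def propensity_records(table: PropensityTable, group: str, detector: str) -> list[dict]:
    return [
        {
            "group": group,
            "detector": detector,
            "fg_label": table.foreground_label,
            "bg_label": table.background_label,
            "groove_scope": table.groove_scope,
            "state3": s,
            "count_fg": table.counts_fg.get(s, 0),
            "count_bg": table.counts_bg.get(s, 0),
            "propensity": round(table.propensity.get(s, 0.0), 4),
        }
        for s in STATE3
    ]
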