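"""End-to-end orchestration over a dataset manifest.

For every manifest entry and every selected detector the pipeline parses
the structure, applies the protein selector, assembles the DNA duplex,
detects protein-DNA hydrogen bonds, and reduces them to a per-complex
strand summary.  Group-level summaries, secondary-structure propensity
tables and the HS-vs-MS statistical comparisons are then derived, and
everything is written as TSV plus a JSON run report.

Entries whose structure file is missing are skipped with a logged error
(the run continues and the report flags partial success); complexes with
zero side chain-base hydrogen bonds stay in the per-complex table with a
flag but never enter percentage-based statistics.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from . import structure_io
from .dna_model import detect_base_pairs
from .group_stats import compare_groups, comparison_record
from .hbond_detect import DetectorParams, bonds_to_records, detect_hbonds
from .propensity import base_contacting_residues, compute_propensity, propensity_records
from .secstruct import assign_secstruct
from .strand_analysis import (
    ComplexSummary,
    complex_summary_record,
    summarize_complex,
    summarize_group,
)
from .structure_io import AnalysisUnit, ManifestEntry

logger = logging.getLogger(__name__)

COMPARISON_METRICS = {
    "pct_dominant_both_grooves": lambda cs: cs.pct_dominant,
    "pct_dominant_major": lambda cs: cs.pct_dominant_major,
    "pct_dominant_minor": lambda cs: cs.pct_dominant_minor,
    "pct_dominant_nonscb": lambda cs: cs.pct_dominant_nonscb,
    "pct_dominant_engaged_bases": lambda cs: cs.pct_dominant_bases,
    "pct_dominant_engaged_bases_major": lambda cs: cs.pct_dominant_bases_major,
}


@dataclass
class RunConfig:
    manifest: str
    structure_dir: str
    detectors: tuple[str, ...] = ("geometric", "energy")
    scope: str = "domain"  # domain | chain (entry ranges apply when domain)
    out_dir: str = "results"
    params: Optional[DetectorParams] = None
    groove_scopes: tuple[str, ...] = ("both", "major")
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not self.detectors:
            raise ValueError("select at least one detector")


@dataclass
class ComplexResult:
    entry: ManifestEntry
    detector: str
    summary: ComplexSummary
    bonds: list
    unit: AnalysisUnit
    secstruct_state3: dict  # residue key -> state3


@dataclass
class ReportBundle:
    results: list[ComplexResult] = field(default_factory=list)
    group_summaries: list = field(default_factory=list)
    comparisons: list = field(default_factory=list)
    propensities: list = field(default_factory=list)
    skipped: list = field(default_factory=list)

    @property
    def partial(self) -> bool:
        return bool(self.skipped)


def _detector_params(detector: str, base: Optional[DetectorParams]) -> DetectorParams:
    if base is None:
        return DetectorParams(method=detector)
    return dataclasses.replace(base, method=detector)


def analyze_entry(
    entry: ManifestEntry, structure_dir: str, detectors, params=None, scope=None
) -> list[ComplexResult]:
    """Run the full per-complex analysis for one manifest entry."""
    path = structure_io.find_structure_file(structure_dir, entry.pdb_id)
    if path is None:
        raise FileNotFoundError(f"no structure file for {entry.pdb_id} in {structure_dir}")
    structure = structure_io.parse_structure(path)
    if scope is not None and scope != entry.scope:
        entry = dataclasses.replace(entry, scope=scope)
    unit = structure_io.apply_selector(structure, entry)
    duplex = detect_base_pairs(unit.dna_strand1, unit.dna_strand2)
    assignment = assign_secstruct(unit.protein_residues)
    state3 = {r.key: s for r, s in zip(assignment.residues, assignment.state3)}
    out = []
    for detector in detectors:
        dp = _detector_params(detector, params)
        bonds = detect_hbonds(unit, dp)
        summary = summarize_complex(bonds, duplex, entry, detector=detector)
        out.append(
            ComplexResult(
                entry=entry,
                detector=detector,
                summary=summary,
                bonds=bonds,
                unit=unit,
                secstruct_state3=state3,
            )
        )
    return out


def _pooled_propensities(results: list[ComplexResult], group: str, detector: str) -> list[dict]:
    """Figure-7-style panels: pooled foreground/background state counts."""
    fg_bc: list[str] = []
    bg_all: list[str] = []
    bg_dna_hb: dict[str, list[str]] = {"both": [], "major": []}
    fg_scb: dict[str, list[str]] = {"both": [], "major": []}
    for res in results:
        if res.entry.group != group or res.detector != detector:
            continue
        st = res.secstruct_state3
        bg_all.extend(st.values())
        for r in base_contacting_residues(res.unit):
            if r.key in st:
                fg_bc.append(st[r.key])
        scb_keys = {"both": set(), "major": set()}
        dna_keys = {"both": set(), "major": set()}
        for hb in res.bonds:
            pk = hb.protein_res.key
            dna_keys["both"].add(pk)
            if hb.groove == "major":
                dna_keys["major"].add(pk)
            if hb.is_sidechain_base:
                scb_keys["both"].add(pk)
                if hb.groove == "major":
                    scb_keys["major"].add(pk)
        for scope in ("both", "major"):
            fg_scb[scope].extend(st[k] for k in scb_keys[scope] if k in st)
            bg_dna_hb[scope].extend(st[k] for k in dna_keys[scope] if k in st)
    records: list[dict] = []
    panels = [
        (fg_bc, bg_all, "base_contacting", "all_domain_residues", "both"),
        (fg_scb["both"], fg_bc, "scb_residues", "base_contacting", "both"),
        (fg_scb["major"], fg_bc, "scb_residues", "base_contacting", "major"),
        (fg_scb["both"], bg_dna_hb["both"], "scb_residues", "all_dna_hbond_residues", "both"),
        (fg_scb["major"], bg_dna_hb["both"], "scb_residues", "all_dna_hbond_residues", "major"),
    ]
    for fg, bg, fg_label, bg_label, scope in panels:
        if not fg or not bg:
            continue
        table = compute_propensity(fg, bg, fg_label, bg_label, scope)
        records.extend(propensity_records(table, group, detector))
    return records


def run_pipeline(config: RunConfig) -> ReportBundle:
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    entries = structure_io.read_manifest(config.manifest)
    bundle = ReportBundle()
    for entry in entries:
        try:
            bundle.results.extend(
                analyze_entry(
                    entry,
                    config.structure_dir,
                    config.detectors,
                    params=config.params,
                    scope=None,
                )
            )
        except FileNotFoundError as exc:
            logger.error("skipping %s: %s", entry.pdb_id, exc)
            bundle.skipped.append({"pdb_id": entry.pdb_id, "reason": str(exc)})
    if not bundle.results:
        raise RuntimeError("zero analyzable manifest entries")

    groups = sorted({r.entry.group for r in bundle.results})
    for detector in config.detectors:
        for group in groups:
            summaries = [
                r.summary
                for r in bundle.results
                if r.detector == detector and r.entry.group == group
            ]
            if summaries:
                bundle.group_summaries.append(summarize_group(summaries))
            bundle.propensities.extend(_pooled_propensities(bundle.results, group, detector))
        # HS vs MS comparisons (the NS group mostly lacks these bonds and is
        # reported through counts only)
        if {"HS", "MS"} <= set(groups):
            for metric, getter in COMPARISON_METRICS.items():
                vals = {}
                for g in ("HS", "MS"):
                    vals[g] = [
                        v
                        for r in bundle.results
                        if r.detector == detector and r.entry.group == g and r.summary.has_scb
                        for v in [getter(r.summary)]
                        if v is not None
                    ]
                if len(vals["HS"]) >= 3 and len(vals["MS"]) >= 3:
                    res = compare_groups(
                        vals["HS"], vals["MS"], metric=f"{metric}[{detector}]",
                        group_a="HS", group_b="MS",
                    )
                    bundle.comparisons.append(res)
    write_outputs(bundle, config)
    return bundle


def write_outputs(bundle: ReportBundle, config: RunConfig) -> None:
    os.makedirs(config.out_dir, exist_ok=True)

    def dump(name: str, records: list[dict]) -> None:
        df = pd.DataFrame.from_records(records)
        df.to_csv(os.path.join(config.out_dir, name), sep="\t", index=False)

    bond_recs = []
    for r in bundle.results:
        bond_recs.extend(bonds_to_records(r.bonds, r.entry.pdb_id, r.detector))
    dump("bonds.tsv", bond_recs)
    dump("complexes.tsv", [complex_summary_record(r.summary) for r in bundle.results])
    dump("groups.tsv", [dataclasses.asdict(g) for g in bundle.group_summaries])
    dump("propensity.tsv", bundle.propensities)
    dump("comparisons.tsv", [comparison_record(c) for c in bundle.comparisons])
    report = {
        "n_entries_analyzed": len({r.entry.pdb_id for r in bundle.results}),
        "n_skipped": len(bundle.skipped),
        "skipped": bundle.skipped,
        "detectors": list(config.detectors),
        "partial": bundle.partial,
    }
    with open(os.path.join(config.out_dir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
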