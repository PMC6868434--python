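#!/usr/bin/env python
"""Strand-level comparisons between the synthetic HS and MS groups.

Reads the per-complex table written by 02_run_pipeline.py, recomputes the
dominant-strand percentage distributions and the normality-gated HS-vs-MS
tests (both grooves, major only, minor only, and the non-side-chain-base
control), and verifies the recovered counts against the planted-truth
summary from 01_simulate_dataset.py.
"""

import argparse
import sys

import pandas as pd

from hbstrand.group_stats import compare_groups, comparison_record


def main(argv=None):
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort-results", default="results/cohort")
    ap.add_argument("--planted", default="results/dataset_planted_summary.tsv")
    ap.add_argument("--out", default="results/strand_statistics.tsv")
    args = ap.parse_args(argv)

    df = pd.read_csv(f"{args.cohort_results}/complexes.tsv", sep="\t")
    planted = pd.read_csv(args.planted, sep="\t").set_index("group")
    rows = []
    for detector in ("geometric", "energy"):
        d = df[(df.detector == detector) & df.has_scb].copy()
        d["pct_major"] = 100.0 * d[["n_scb_major_s1", "n_scb_major_s2"]].max(axis=1) / (
            d.n_scb_major_s1 + d.n_scb_major_s2
        )
        d["pct_minor"] = 100.0 * d[["n_scb_minor_s1", "n_scb_minor_s2"]].max(axis=1) / (
            d.n_scb_minor_s1 + d.n_scb_minor_s2
        )
        d["pct_nonscb"] = 100.0 * d[["n_nonscb_s1", "n_nonscb_s2"]].max(axis=1) / (
            d.n_nonscb_s1 + d.n_nonscb_s2
        )
        for metric in ("pct_dominant", "pct_major", "pct_minor", "pct_nonscb"):
            hs = d.loc[d.group == "HS", metric].dropna()
            ms = d.loc[d.group == "MS", metric].dropna()
            if len(hs) >= 3 and len(ms) >= 3:
                rec = comparison_record(
                    compare_groups(hs, ms, metric=f"{metric}[{detector}]",
                                   group_a="HS", group_b="MS")
                )
                rec["mean_HS"] = round(hs.mean(), 2)
                rec["mean_MS"] = round(ms.mean(), 2)
                rows.append(rec)
        # recovered counts must equal the planted cohort statistics
        if detector == "geometric":
            for group in ("HS", "MS"):
                g = df[(df.detector == detector) & (df.group == group)]
                eq = int(g[g.has_scb].is_5050_bonds.sum())
                assert eq == int(planted.loc[group, "equal"]), (
                    f"{group}: recovered 50/50 count {eq} != planted "
                    f"{planted.loc[group, 'equal']}"
                )
    out = pd.DataFrame(rows)
    out.to_csv(args.out, sep="\t", index=False)
    print(out.to_string(index=False))
    print("\nrecovered 50/50 counts match the planted cohort exactly")
    print(f"comparison table: {args.out}")


if __name__ == "__main__":
    sys.exit(main())
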