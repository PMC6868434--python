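#!/usr/bin/env python
"""Secondary-structure propensity on ideal-geometry peptides with planted
labels.

Builds helix/sheet/coil peptides, assigns secondary structure with the
Kabsch-Sander implementation, then computes propensities for a foreground
deliberately enriched in strand+coil against the full background -- the
synthetic analogue of comparing DNA-contacting residues against all domain
residues.  The recovered propensities must show the planted enrichment.
"""

import argparse
import sys

import numpy as np
import pandas as pd

from hbstrand.propensity import compute_propensity
from hbstrand.secstruct import assign_secstruct
from hbstrand.synthetic_data import build_helix, build_peptide, build_sheet, PHI_PSI


def main(argv=None):
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", default="results/propensity_synthetic.tsv")
    args = ap.parse_args(argv)
    rng = np.random.default_rng(args.seed)

    segments = []
    for _ in range(6):
        segments.append(("helix", assign_secstruct(build_helix(12)).state3))
    for _ in range(6):
        segments.append(("strand", assign_secstruct(build_sheet(6)).state3))
    for _ in range(6):
        segments.append(("coil", assign_secstruct(build_peptide([PHI_PSI["coil"]] * 10)).state3))

    background = [s for _, states in segments for s in states]
    # foreground: all strand/coil-segment residues plus a 20% draw of
    # helix-segment residues (strand/coil-biased "interface")
    fg = []
    for kind, states in segments:
        take = 1.0 if kind in ("strand", "coil") else 0.2
        for s in states:
            if rng.random() < take:
                fg.append(s)
    table = compute_propensity(fg, background, "interface_like", "all_residues")
    df = pd.DataFrame(
        [
            {
                "state3": s,
                "freq_fg": round(table.freq("fg", s), 4),
                "freq_bg": round(table.freq("bg", s), 4),
                "propensity": round(table.propensity[s], 4),
            }
            for s in ("helix", "strand", "coil")
        ]
    )
    df.to_csv(args.out, sep="\t", index=False)
    print(df.to_string(index=False))
    assert table.propensity["strand"] > 1.0 > table.propensity["helix"], (
        "planted strand/coil enrichment not recovered"
    )
    print("\nplanted enrichment recovered: strand/coil up, helix down")
    print(f"table: {args.out}")


if __name__ == "__main__":
    sys.exit(main())
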