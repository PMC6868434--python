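#!/usr/bin/env python
"""Worked examples on real crystal structures, when available locally.

NgoMIV endonuclease (4ABT, protein chain A vs DNA chains E/H) should show
three or more consecutive Watson-Crick pairs engaged on both bases in the
major groove; the E. coli sigma(E)4 domain (2H27, chain A vs B/C) engages
equal numbers of bases on the two strands but no complete pair.

Looks for coordinate files in data/pdb_mirror/ (e.g. data/pdb_mirror/4abt.pdb).
No network access is attempted: if the files are absent the script reports
that and exits cleanly.
"""

import argparse
import os
import sys

from hbstrand.dna_model import detect_base_pairs
from hbstrand.hbond_detect import detect_hbonds_geometric
from hbstrand.strand_analysis import find_basepair_hbonds, summarize_complex
from hbstrand.structure_io import ManifestEntry, apply_selector, find_structure_file, parse_structure

EXAMPLES = [
    ("4abt", "HS", "A", ("E", "H")),
    ("2h27", "MS", "A", ("B", "C")),
]


def main(argv=None):
    ap = argparse.ArgumentParser()
    ap.add_argument("--mirror", default="data/pdb_mirror")
    args = ap.parse_args(argv)

    for pdb_id, group, chain, dna in EXAMPLES:
        path = find_structure_file(args.mirror, pdb_id)
        if path is None:
            print(f"{pdb_id}: not in {args.mirror}/ -- place the PDB file there to run this example")
            continue
        structure = parse_structure(path)
        entry = ManifestEntry(pdb_id, group, chain, None, dna, "chain")
        unit = apply_selector(structure, entry)
        duplex = detect_base_pairs(unit.dna_strand1, unit.dna_strand2)
        bonds = detect_hbonds_geometric(unit)
        cs = summarize_complex(bonds, duplex, entry)
        pairs = find_basepair_hbonds(bonds, duplex, "major")
        print(f"{pdb_id} ({group}): scb bonds {cs.n_scb_strand1}/{cs.n_scb_strand2}, "
              f"engaged bases (major) {len(cs.engaged_bases_major_s1)}/{len(cs.engaged_bases_major_s2)}, "
              f"engaged pairs (major): {len(pairs)}")
        for p in pairs:
            print(f"    {p.res_i.label()} . {p.res_j.label()}  [{p.pair_type}]")
    return 0


if __name__ == "__main__":
    sys.exit(main())
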