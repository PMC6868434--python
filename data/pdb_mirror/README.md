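# Local PDB mirror

Coordinate files for analyses on real structures go here; nothing in this
directory is fetched automatically and no network access is attempted by
the tests or scripts.

* Worked examples (`analysis/05_worked_examples.py`,
  `tests/test_acceptance.py::test_worked_examples_ngomiv_and_sigmaE4`):
  place `4abt.pdb` and `2h27.pdb` (PDB or mmCIF format, any filename case,
  e.g. from https://files.rcsb.org/download/4ABT.pdb).

* Dataset-level run
  (`tests/test_acceptance.py::test_dataset_level_group_counts`): place the
  curated specificity manifest as `manifest.tsv` (columns
  `pdb_id, group, protein_selector, dna_chains, scope`) plus the
  referenced structure files.

Crystal structures are not redistributed with this repository.
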