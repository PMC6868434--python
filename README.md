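# hbstrand

Strand-level analysis of side chain–base hydrogen bonds in protein–DNA
complexes.

## The scientific problem

DNA-binding proteins span a specificity spectrum: type II restriction
endonucleases recognize one short sequence (highly specific, **HS**),
transcription factors tolerate variation at some positions of their motif
(multi-specific, **MS**), and histones or polymerases bind DNA with little
sequence preference (non-specific, **NS**).  The dominant physical signal
for base readout is the hydrogen bond between an amino-acid *side chain*
and a DNA *base* edge (sugar/phosphate contacts mostly buy affinity, not
specificity).  This package asks how that signal is distributed over the
**two strands** of the DNA double helix:

* for each complex, count side chain–base hydrogen bonds per strand and
  per groove; the strand with more bonds is the **dominant strand**, with
  percent contribution 100·max(n₁,n₂)/(n₁+n₂); equal nonzero counts make a
  **50/50 case**;
* find **engaged base pairs** — Watson–Crick pairs in which *both* bases
  accept or donate at least one side chain–base hydrogen bond;
* compare HS and MS groups with a Shapiro–Wilk-gated two-sample test
  (Student's t when both samples look normal, Wilcoxon rank-sum
  otherwise), with backbone-contact counts as a negative control;
* relate interacting residues to their secondary structure (Kabsch–Sander
  assignment reduced to helix/strand/coil) via propensity ratios
  f_fg(s)/f_bg(s).

Hydrogen bonds are detected two independent ways so conclusions do not
hinge on one criterion: a geometric detector (donor–acceptor ≤ 3.9 Å,
H···acceptor ≤ 2.5 Å, D–H–A and H–A–antecedent angles ≥ 90°) and the Mayo
12-10 potential E = V₀{5(d₀/d)¹² − 6(d₀/d)¹⁰}·F(θ,φ,γ) with V₀ = 8
kcal/mol, d₀ = 2.8 Å and hybridization-dependent angular factors, keeping
bonds with E ≤ −0.6 kcal/mol.  Polar hydrogens are rebuilt at ideal
geometry, so structures deposited with and without hydrogens are treated
identically.

## Worked example

The analysis is organised as numbered drivers over the library:

```sh
python analysis/01_simulate_dataset.py --seed 1   # 32 HS + 115 MS + 52 NS synthetic complexes
python analysis/02_run_pipeline.py                # both detectors, all tables
python analysis/03_strand_statistics.py           # HS-vs-MS comparisons
python analysis/04_secstruct_propensity.py        # propensity on planted peptides
```

Script 02 prints, per group and detector (seed 1):

```
HS/geometric n= 32 with_scb= 32 equal=  8 (25.0%) one_strand=  0 ( 0.0%) >=1bp= 20 GC= 13 AT= 13
MS/geometric n=115 with_scb=115 equal=  0 ( 0.0%) one_strand= 41 (35.7%) >=1bp=  6 GC=  4 AT=  2
NS/geometric n= 52 with_scb= 10 equal=  2 (20.0%) one_strand=  8 (80.0%) >=1bp=  0 GC=  0 AT=  0
```

reading: all 32 HS-like complexes form side chain–base bonds, 8 with
exactly equal strand contributions, 20 with at least one fully engaged
base pair; the MS-like group is skewed (41 of 115 complexes bond one
strand only); 42 of 52 NS-like complexes have no side chain–base bond at
all.  Script 03 then shows the dominant-strand percentage separating HS
from MS in both grooves combined (rank-sum p ≈ 9·10⁻¹², means 60% vs 81%)
and in the major groove alone, no separation in the sparse minor groove,
and p = 1.0 on the backbone-bond control — the strand balance is a
base-readout property, not a bulk-contact one.  Because every synthetic
complex carries planted ground truth, script 03 also verifies the
recovered 50/50 counts equal the planted ones exactly.

With real structures in `data/pdb_mirror/`, `analysis/05_worked_examples.py`
analyzes the NgoMIV endonuclease (4ABT, chain A vs DNA chains E/H;
expected: ≥3 consecutive engaged pairs in the major groove) and the
*E. coli* sigma(E)4 domain (2H27, chain A vs B/C; expected: equal engaged
bases per strand, zero engaged pairs).

A `hbstrand` console command exposes the same pipeline
(`hbstrand analyze --manifest ... --structures ...`, `hbstrand fixtures`,
`hbstrand stats`).

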