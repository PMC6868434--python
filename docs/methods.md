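# Methods

## Scope and data model

The package analyzes protein–dsDNA complexes given as PDB/mmCIF files plus
a manifest (TSV: `pdb_id, group, protein_selector, dna_chains, scope`)
naming, per complex, the specificity group (HS/MS/NS), the protein chain
with an optional inclusive author-numbered domain range (`D:3-226`), and
the two DNA chains.  Parsing (gemmi) keeps author chain ids and numbering,
flags waters/ligands as `other`, collapses altloc groups to the
highest-occupancy conformer (alphabetical tie-break), and **discards input
hydrogens** — polar hydrogens are re-placed at ideal geometry so that
X-ray entries with and without deposited hydrogens are processed
identically.  Chains are classified protein/dna by an 80%
residue-composition majority, which tolerates modified residues.  A small
set of modified bases (5CM, 8OG, BrdU, dU, ...) maps to its parent
canonical base; unmapped exotic nucleotides are excluded from base-level
counts.

## Watson–Crick pairing and groove edges

Base pairs are detected geometrically: identity complementarity (A–T,
G–C), purine N1–pyrimidine N3 distance ≤ 3.5 Å, C1′–C1′ distance in
[9.0, 11.5] Å, each base in at most one pair with conflicts resolved
greedily by smallest N1–N3 distance.  These thresholds accept canonical
Watson–Crick geometry (ideal B-DNA gives N1–N3 ≈ 2.96–3.0 Å and C1′–C1′ ≈
10.7 Å) and reject stacked or bulged arrangements; Hoogsteen and mismatch
pairs are deliberately out of scope.  Groove labels come from a fixed
table of hydrogen-bond-capable edge atoms — major: A{N6,N7}, G{O6,N7},
C{N4}, T{O4}; minor: A{N3}, G{N3,N2}, C{O2}, T{O2} — with Watson–Crick
edge atoms (purine N1, pyrimidine N3) and all sugar/phosphate atoms
mapping to `none`.  The table is restricted to donor/acceptor-capable
atoms because groove labels are only ever attached to hydrogen bonds.

## Hydrogen-bond detection

Donor/acceptor chemistry covers every polar side-chain group of Arg, Lys,
His, Asn, Gln, Ser, Thr, Tyr, Trp (plus Asp/Glu as acceptors), backbone
N/O, all base edge donors/acceptors, and the phosphate/sugar oxygens.
Hydrogen placement: N–H 1.00 Å, O–H 0.96 Å; amide NH₂ at in-plane ±120°
from the N–C bond; ring N–H along the external bisector; backbone amide H
opposite the bisector of the preceding C and CA (skipped for prolines,
chain starts and breaks); Ser/Thr/Tyr hydroxyls and Lys ammonium are
oriented toward the nearest acceptor within 3.9 Å, else staggered.
Donors with missing antecedents are skipped with a logged warning.

*Geometric detector* (HBPLUS-style defaults, exposed as parameters):
donor–acceptor ≤ 3.9 Å, H···acceptor ≤ 2.5 Å, θ(D–H–A) ≥ 90°,
θ(H–A–antecedent) ≥ 90°; one bond per donor–acceptor atom pair (best
hydrogen).  *Energy detector*: candidates pre-screened at D–A ≤ 4.5 Å and
θ ≥ 90°, scored with the Mayo 12-10 well on the donor–acceptor distance
(V₀ = 8 kcal/mol, d₀ = 2.8 Å, minimum −V₀ at d₀) times an angular factor
by hybridization pair — sp3/sp3 cos²θ·cos²(φ−109.5°), sp3 donor/sp2
acceptor cos²θ·cos²φ, sp2/sp3 cos⁴θ, sp2/sp2 cos²θ·cos²(max(φ,γ)) with γ
the out-of-plane angle of the H→A approach at the acceptor — and kept at
E ≤ −0.6 kcal/mol, the cutoff conventional for rigidity analysis with
this potential.  His ND1/NE2 are treated as both donor and acceptor
(X-ray data cannot resolve protonation); at most one bond is kept per His
nitrogen and partner.  Bidentate contacts count as distinct bonds; bonds
and engaged bases are tracked separately.

Each bond is classified by its protein atom (side chain vs backbone
{N, CA, C, O, OXT}) and DNA atom (base vs sugar/phosphate), giving the
four interaction classes; groove labels apply only to base atoms.

## Strand bookkeeping

Per complex: side chain–base bond counts per strand (total and per
groove), engaged-base sets, summed bond energies per strand (energy
detector), backbone/non-side-chain-base counts as the affinity control,
dominant-strand percentage, and two distinct 50/50 notions — equal
nonzero *bond* counts, and equal nonzero *engaged-base* counts in the
major groove — because the comparative analysis uses both.  Dominant-
strand ties break deterministically toward strand 1 and set the 50/50
flag (either strand may equally be called dominant).  Engaged base pairs
are Watson–Crick pairs whose both bases carry ≥ 1 side chain–base bond
passing the groove filter; pairs are counted as pairs (not bonds) and
typed GC/AT.  "No more than 75%" is inclusive (≤ 75).  Complexes with
zero side chain–base bonds stay in the per-complex table but are excluded
from every percentage denominator.

## Secondary structure and propensity

Kabsch–Sander is re-implemented: backbone C=O···H–N energy
E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol, bond iff
E < −0.5, with the amide H 1.0 Å from N anti-parallel to the preceding
carbonyl; n-turns at offsets 3/4/5 give G/H/I, bridge patterns give
B and (laddered) E, remaining turn/bend positions T/S; priority H, then
E/B, then G/I, then T/S; Cα–Cα > 4.5 Å terminates segments.  The 3-state
reduction is exact and total: helix = {H,G,I}, strand = {E,B}, everything
else (including polyproline states from newer assigners) coil.  A reader
for classic DSSP output allows cross-checks at the 3-state level; version
differences in G/H tie-breaking make 8-state parity uninteresting.

DNA base-contacting residues have ≥ 1 side-chain heavy atom within 4.5 Å
of a base heavy atom (backbone contacts and glycine never qualify).
Propensity(s) = [count_fg(s)/|fg|]/[count_bg(s)/|bg|] over
helix/strand/coil, pooled across complexes of a group (a residue counts
once per complex occurrence); an empty background frequency with nonzero
foreground is flagged infinite.  The pipeline emits the standard panels:
base-contacting vs all domain residues, and side chain–base bonding
residues (both grooves / major only) vs base-contacting or vs all
DNA-bonded residues.

## Group comparison

Two-sample comparisons are gated on normality: Shapiro–Wilk on each
sample at α = 0.05 (the conventional default; zero-variance samples count
as non-normal); both pass → two-sided Student's t, otherwise two-sided
Wilcoxon rank-sum.  The unit of observation is one complex (its
dominant-strand percentage, engaged-base percentage, etc.); raw p-values
are reported without multiple-testing correction.  Calibration: over 2000
null Gaussian simulations (n = 30 per group) the gated procedure rejects
at 0.047–0.061 depending on seed, consistent with its nominal 0.05 size.

## Synthetic data

`generate_bdna` builds an idealized B-form duplex by fiber-model stacking
(rise 3.38 Å, twist 36°/step) of published standard-reference-frame base
geometries, with the complementary strand generated by the pair dyad
(x, −y, −z).  Base-edge geometry is exact — every constructed pair passes
the Watson–Crick detector — while the sugar–phosphate moiety is schematic
(exact C1′ anchor plus an approximately placed phosphate group); backbone
torsions are not modelled and no analysis reads them.

`plant_probe` drops free-floating amino-acid fragments (with backbone
stubs so interaction-class logic is exercised) at chosen base-edge or
phosphate targets.  Bond probes sit at donor–acceptor 2.9 Å along the
acceptor's lone-pair direction (carbonyl extension for single-neighbour
atoms, external ring bisector for N3/N7), collinear D–H···A; fragments
are fixed-geometry Asn (toward base acceptors) or Asp (receiving base
amine donors) in randomized fixtures, so no rotamer search can reroute a
planted bond, with Ser/Arg variants for targeted tests.  Near-miss probes
perturb one planted criterion — distance to 4.2 Å, or the D–H–A angle to
< 90° (in-plane rotation clear of both amine hydrogens and of the partner
strand); note the dependent H···A distance degrades alongside the
perturbed criterion, as it must for a rigid fragment.  Probed pairs are
kept ≥ 2 helical steps apart (except deliberate both-bases-of-one-pair
plantings) so planted geometries stay independent; this is what makes
exact ground-truth recovery a meaningful test.

The cohort generator emulates the study conditions at the paper-scale
group sizes (32 HS, 115 MS, 52 NS): HS-like complexes engage both strands
nearly equally (strand-count difference 0/1/2 with probability
.34/.46/.20) and often both bases of a major-groove pair; MS-like
complexes are skewed (38% one-strand-only) with rare engaged pairs;
NS-like complexes mostly (34/52) lack side chain–base bonds, the
remainder favouring the minor groove.  All groups receive
strand-balanced phosphate contacts as the control population.  Secondary
structure fixtures are separate ideal-geometry peptides (helix φ/ψ
−57/−47; sheet strands −119/+113 with the antiparallel partner placed by
numeric refinement of the O···N ladder; coil −75/+145).

**What passing synthetic tests does and does not show.**  The fixtures
validate the machinery — detection geometry, strand/groove attribution,
pair bookkeeping, statistics — under ideal coordinates with planted
truth.  They do not probe crystallographic noise, water-mediated or
bifurcated bonds, non-B DNA, or real rotamer ambiguity, and the group
contrast in the cohort is planted rather than discovered; conclusions
about real HS/MS biology require running the pipeline on the curated PDB
dataset (see `data/pdb_mirror/README.md`).

## Numerical choices and limitations

Problem sizes in the shipped drivers and acceptance script (100 planted
fixtures, 199-complex cohort, 2000 calibration simulations) were chosen
so a full run completes in well under a minute on one core; all
randomness is seed-derived.  Degenerate inputs: chains shorter than 3
residues assign all-coil; empty bond lists are legal everywhere;
zero-variance samples take the rank-sum branch.  Known limitations: the
exact criteria of the reference hydrogen-bond annotators are not
published to the last detail, so per-complex bond lists on real
structures may differ slightly from theirs even where group-level
patterns agree; phosphate geometry in fixtures is schematic; solvent
accessibility and the remainder of the DSSP feature set are not
computed.
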