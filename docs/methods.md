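# Methods

## The model system

An amyloid steric zipper is a pair of self-complementary β-sheets whose
side chains interdigitate in a dry interface; each sheet is a stack of
short peptide strands related by a translation of one *rise* (~4.8 Å)
along the fibril axis. Fibrils grow by adding strands at the two exposed
ends. A capping inhibitor exploits this: it is threaded to bind a tip
exactly as the next incoming monomer would, but carries modifications that
(i) sterically clash with the incoming strand of the *mating* sheet
(Trp substitution at an interface position), (ii) delete a hydrogen-bond
donor needed by the next layer (backbone N-methylation), or (iii) stack
charged tags that repel further copies (poly-lysine, TAT). The package
models this end to end for the α-synuclein NACore zipper and for arbitrary
zipper-forming sequences.

## Ideal-zipper fixture

`fixtures.build_ideal_zipper` generates a parallel, in-register homo-zipper
from a sequence. The backbone is a schematic extended strand: per residue,
fixed offsets for N, CA, C, O and the amide H in the strand frame
(x = strand direction, z = fibril axis), with a residue spacing of 3.5 Å.
The offsets were chosen so that the inter-layer N(i)···O(i−1) distance is
3.08 Å — a counted β-sheet hydrogen bond that sits just outside steric
overlap under the radius table below. Side chains are placed on fixed
schematic templates (CB 1.53 Å along the alternating sheet normal, heavier
atoms at approximate bonded geometry); they have roughly correct reach and
bulk but are not rotamer-library conformers. Sheet B is sheet A rotated
180° about the fibril axis (chirality-preserving; all residues stay L),
offset by half a residue spacing along the strand, half a rise along the
axis, and the sheet separation (default 8.5 Å between backbone planes)
across. Defaults (rise 4.8 Å, separation 8.5 Å) are canonical steric-zipper
dimensions.

What the fixture emulates: the lattice periodicity, two-sheet architecture,
β-sheet H-bond ladder, interface side-chain packing and the two distinct
growth ends. What it does not: crystallographic side-chain rotamers,
backbone pleat detail, waters, and any particular deposited entry's
coordinates. Tests that pass on the fixture therefore validate the
*operations* (threading, scoring, symmetry handling) and ordinal claims,
not atomic accuracy on real structures.

Synthetic assay generators produce steady-state isotherms from the 1:1
model plus Gaussian noise (default 11 log-spaced concentrations, 0.5–500
µM — the instrument range used for the characterized panel), and logistic
ThT time courses whose inhibited plateau is the control plateau divided by
a known fold. The logistic family is a convenience: only endpoint ratios
are ever analyzed, never kinetic parameters.

## Radii and score terms

Clash, buried area and shape complementarity use a fixed united-atom
element radius table (Chothia-style: C 1.87, N 1.65, O 1.40, S 1.85 Å),
appropriate for hydrogen-less heavy-atom models; hydrogens are excluded
from sterics. With these radii the 3.08 Å H-bond is not a clash, and the
schematic lattice is tightly packed, as a real zipper is.

- **clash** — soft quadratic overlap Σ max(0, r_a + r_b − d)² over
  cross-interface heavy-atom pairs.
- **hbond_count** — backbone N–H···O=C pairs across the interface with
  N···O ≤ 3.5 Å; when the amide hydrogen is modeled it must also point at
  the acceptor (H···O ≤ 2.6 Å), which suppresses spurious pairs in shifted
  poses; each donor counts at most once. N-methylation and proline remove
  the donor. Models without explicit hydrogens fall back to the N···O
  criterion alone.
- **buried_surface_area** — Shrake–Rupley SASA with a 1.4 Å probe and a
  deterministic golden-spiral point lattice (default 256 points/atom;
  doubling from 512 to 1024 changes the fixture BSA by < 0.3%). Fibril
  atoms out of reach of the pose are skipped exactly (occlusion always uses
  the full atom set).
- **shape_complementarity** — dots on the exposed vdW surfaces (default
  ≈ 15 dots/Å²); for each dot in the buried band (nearest partner dot
  ≤ 1.5 Å) score exp(−w·d²)·(n̂_a·(−n̂_b)) with w = 0.5 Å⁻²; Sc is the mean
  of the two per-surface medians, undefined when there is no buried band.
- **electro_stack_penalty** — max(0, q₁·q₂) over net formal charges
  (K/R = +1, D/E = −1; termini treated as capped, as synthetic peptides
  usually are). Tags are scored only through this term: disordered
  poly-K/TAT tails have no defined structure worth building. The TAT
  default `YGRKKRRQRRR` (net +8) is an assumption, configurable.
- **composite energy** — w_c·clash − w_h·hbonds − w_b·BSA − w_s·Sc +
  w_e·electro with defaults (4, 2, 0.05, 10, 1). Units are arbitrary;
  every downstream claim is ordinal (rankings, verdicts), so only the
  relative balance matters: with these defaults the native self-extension
  pose scores about −47, H-bonds and buried area contribute comparably,
  and a 3 Å displacement is decisively worse.

**Mating-sheet disruption.** The design goal of a Trp at an interface
position is to clash with the *incoming* strand of the opposing sheet, not
with atoms that already exist (a pose clashing with the existing fibril
simply would not bind). The two are therefore separated: `clash` is scored
against existing context atoms and enters the binding energy;
`mating_disruption` is the same soft overlap against a virtual strand
placed at the opposing sheet's next lattice site (its outermost strand
translated one rise outward) and is *rewarded* by the design objective
(weight `mating_disrupt`, default 0 so the binding composite is unchanged
unless design is asked for).

## Threading, optimization, redesign

Threading copies the tip template backbone one rise outward, rebuilds side
chains from the schematic templates in the local strand frame (strand
direction from consecutive CAs, outward sign from the template's own CBs
with parity fill-in at glycines), replaces the amide H with a methyl
carbon at N-methylated positions, and validates spans. For the native
sequence this reproduces the next fibril layer exactly.

Rigid optimization is deterministic greedy coordinate descent: steepest
move among ±0.4/0.2/0.1 Å translations and ±4/2/1° rotations (bounded at
1 Å / 10° from the start), translations settled before rotations and the
two phases alternated — interleaving lets a greedy search trade a small
tilt against a lateral slip and wander off register. The inner objective
replaces the dot-sampled BSA term with a smooth backbone-to-backbone
contact Gaussian (dot-sampled areas are piecewise constant in the
displacement and trap a greedy search in sampling ripple) and the integer
H-bond count with a smooth directional Gaussian in the H···O distance
(peak 2.1 Å, width 0.4 Å); the Sc statistic is a selection criterion, not
a packing force, and stays out of the loop. Steric clash is steepened
(×20) so that burying cannot pay for overlap. On the ideal fixture the
threaded native pose is an exact fixed point of this search, and poses
displaced 0.8 Å along any axis recover the register to machine precision.
A final guard re-scores the result with the full composite and returns the
input pose unchanged if the search did not improve it, so the reported
energy never increases. Discrete rotamer moves are χ1 rotations of ±120°
about CA–CB. The `seed` argument is accepted and logged for interface
uniformity; the search itself uses no randomness.

Fix-and-redesign is the iterative greedy loop: each round evaluates every
single-position substitution over the per-position alphabet (threading +
full scoring, design objective = composite − mating-disruption reward),
fixes the best residue at its position, and continues on the remaining
positions; the trajectory energy is asserted non-increasing, and every
evaluated sequence is returned ranked. On objectives that are separable
across positions this greedy procedure provably matches exhaustive
enumeration, which the tests check on two-position toys.

## Structure input

Parsing goes through gemmi (PDB and mmCIF; unit cell, space-group
operators, author numbering preserved). Alternate locations keep the first
conformer (altloc 'A'); the choice is logged. Waters and non-protein
heterogens are dropped; chains with a peptide-bond break (C–N > 2.5 Å) are
split into separate strands. Symmetry expansion picks the operation whose
Cartesian translation is a plausible strand rise — a pure-translation
symmetry operation or a 3–6.5 Å lattice vector, whichever is closest to
4.8 Å, falling back to screw axes — and errors with instructions to supply
axis/rise manually when none qualifies. Axis detection clusters pairwise
strand translations (tolerance 0.2 Å / 5°) after verifying
translation-superposability of the strand backbones, so the two sheets
(related by rotation, not translation) never contaminate the estimate;
sheet assignment is the connected components under ±rise translations and
must yield exactly two stacks.

Tip extraction takes the extreme strand along the axis on each face as the
template, `context_layers` strands of its own sheet as the binding context
(default 4 — enough layers that BSA and Sc are stable while keeping pair
counts linear), and opposing-sheet strands within 12 Å of the capping site
as the mating surface.

## Assay models

The steady-state SPR fit minimizes least squares for
Req = C·Rmax/(KD + C) + RI with multi-start KD₀ ∈ {min C, median C,
max C}, bounds KD, Rmax > 0, RI free (RI is a fitted parameter, not fixed
at zero, because the bulk refractive-index offset is part of the model).
`se_kd` comes from the covariance at the optimum; `converged` is false for
monotone-decreasing (non-binding) data or a bound-limited optimum. ThT
fold-reduction subtracts each trace's t = 0 value and takes the
control/treated ratio of mean fluorescence over the final 20% of
timepoints (the endpoint window is a package choice; only plateau ratios
are claimed). Complete inhibition (non-positive treated plateau) reports
infinity rather than a number. Puncta normalization divides raw counts by
confluence and summarizes per condition with mean and sample SD
(ddof = 1). Dilution chains compose ratio steps (1:f) and volumetric steps
(v into V) multiplicatively.

## Problem sizes and numerical choices

Tests and examples run on a 4-layer, 9-residue fixture (520 atoms) with
2-layer tip contexts, 120-point SASA sampling and 4 dots/Å² Sc inside
loops; reported scores in examples use the same reduced sampling, and the
dense-sampling defaults (256 points, 15 dots/Å²) are used for one-shot
scoring. These sizes keep the whole suite under a minute while leaving
every assertion's margin far above the sampling differences. The
acceptance script fits 200 synthetic isotherms (two affinities × 100
replicates) with replicate seeds derived from the user seed.

Degenerate inputs: single-strand models raise an ambiguous-axis error;
tips with no mating atoms score zero disruption; Sc is a None flag (never
a number) without a buried band; a non-finite starting score makes
`optimize_pose` return the input flagged `optimization_failed` instead of
raising.

## Known limitations

- The fixture's side chains are schematic; absolute energies, areas and Sc
  values are internally consistent but not comparable across force fields
  or to experimental interface statistics.
- Only parallel in-register homo-zippers are generated; hetero-zipper
  polymorphs are out of scope (real α-synuclein polymorphs include them).
- Tags are charge-only; tag-length or terminus effects beyond net charge
  are invisible to the score.
- The greedy search explores single substitutions per round; strongly
  coupled double mutations can be missed, as with any coordinate-wise
  design loop.
- Crystal-packing interfaces beyond the dual-sheet protofilament are not
  excluded automatically when a deposited structure contains them.
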