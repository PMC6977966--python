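# zippercap

Structure-based design and evaluation of **capping peptide inhibitors** for
amyloid steric-zipper protofilaments, with the quantitative assay models
used to characterize them. The template system is the α-synuclein **NACore**
zipper (residues 68–78, `GAVVTGVTAVA`), whose aggregation drives
Parkinson's-disease-associated seeding; the design register is the
9-residue segment 69–77 (`AVVTGVTAV`).

The package is for structural bioinformaticians and protein designers who
want a transparent, dependency-light re-implementation of the capping
strategy: a peptide is threaded onto the growth end ("tip") of a fibril so
that it binds like the next incoming monomer but — through a bulky
substitution, a backbone N-methylation, or a charged tag — blocks further
growth of one or both β-sheets.

## What it computes

**Fibril geometry.** A steric zipper is two tightly mated β-sheets, each a
stack of strands related by a translation of rise *d* ≈ 4.8 Å along the
fibril axis. `zipper.py` reads PDB/mmCIF structures (via gemmi), expands
crystal symmetry into a finite lattice, detects the axis and rise, and
extracts the top/bottom tip interfaces. `fixtures.py` builds idealized
zippers parametrically so everything runs with no downloads.

**Capping design.** `design.py` threads a candidate onto a tip (backbone =
template strand shifted one rise outward), optimizes the pose by
deterministic coordinate descent (rigid moves ≤ 1 Å / 10° plus χ1 rotamer
swaps), and runs fix-and-redesign: scan single-position substitutions, fix
the best, repeat. `scoring.py` scores each pose:

- clash: Σ max(0, r_vdw(a) + r_vdw(b) − d_ab)² over interface heavy-atom pairs
- H-bonds: backbone N–H···O=C pairs across the interface
  (N···O ≤ 3.5 Å; an N-methylated position has no donor)
- buried surface area (BSA): Shrake–Rupley SASA difference, probe 1.4 Å
- shape complementarity (Sc): Lawrence–Colman-style statistic in [−1, 1]
- electrostatic stacking penalty: net formal charge product of stacking
  partners, clipped at 0
- composite energy
  E = w_c·clash − w_h·hbonds − w_b·BSA − w_s·Sc + w_e·electro
  (arbitrary units, lower = better binding)

A *mating-sheet disruption* term — the clash a bound pose would make with
the next incoming strand of the opposing sheet — is reported separately and
rewarded by the design objective: it is the mechanism that stops fibril
growth.

**Assay models.** `assays.py` implements the steady-state SPR fit

    Req(C) = C·Rmax / (KD + C) + RI

(multi-start least squares; KD in µM, Rmax/RI in response units), ThT
endpoint fold-reduction (baseline-subtracted plateau ratio), puncta-per-well
confluence normalization, and dilution-chain arithmetic.

## Worked example

Rank the four characterized inhibitor specifications (S37, S61, S62 with a
Trp replacing Thr72; S71 with N-methylated Gly73; poly-K or TAT solubility
tags) on an ideal NACore zipper:

```bash
python examples/design_capping_inhibitors.py
```

```
label  sequence best_face     energy  binds_top  binds_bottom  hbonds  mating_disruption  self_aggregation_prone
  S37 AVVWGVTAV    bottom -49.318453       True          True       8           3.362986                   False
  S61 AVVWGVTAV    bottom -49.318453       True          True       8           3.362986                   False
  S62 AVVWGVTAV    bottom -49.318453       True          True       8           3.362986                   False
  S71 AVVTGVTAV    bottom -48.351721       True          True       8           0.000000                   False
```

The Trp-containing designs share one core sequence, so they score
identically against the fibril and differ only in tag-driven
self-aggregation behavior; their nonzero `mating_disruption` is the
designed steric block of the opposing sheet. Energies are ordinal — the
package makes no attempt to reproduce any force-field's absolute values.

Fit a synthetic high-affinity isotherm:

```bash
python examples/fit_spr_affinity.py
```

```
fitted KD = 0.533 µM (se 0.11), Rmax = 95.41 RU, RI = 6.95 RU, converged = True
```

Other examples: `tht_fold_reduction.py` (endpoint fold of an inhibited
aggregation curve), `puncta_and_dilution.py` (cell-seeding bookkeeping,
including the 50 µM → 125 nM transfection chain).

A `zippercap` CLI wraps the same operations (`fixtures`, `design`, `score`,
`fit-kd`, `tht-summary`, `puncta`); see `zippercap --help`.

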