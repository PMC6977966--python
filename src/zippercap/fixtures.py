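"""Parametric generators of idealized zipper fibrils and synthetic assay data.

These fixtures stand in for downloaded crystal structures and instrument
output so that the whole pipeline runs self-contained. The ideal zipper is a
schematic parallel in-register homo steric zipper: two facing β-sheets of
extended strands stacked at a fixed rise along +z, with side chains placed on
fixed idealized templates. Canonical zipper dimensions (rise 4.8 Å, sheet
separation 8.5 Å) are the defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .assays import BindingIsotherm, ThTTrace
from .atoms import AA1_TO_3, AtomRecord, side_chain_template
from .errors import ValidationError
from .zipper import ZipperModel

#: Backbone offsets within one residue of an idealized extended strand,
#: relative to CA, in the strand frame (x = strand direction, z = fibril
#: axis). Chosen so that the inter-layer N(i)···O(i-1) distance is 3.08 Å:
#: a counted β-sheet hydrogen bond that sits just outside vdW overlap.
_BACKBONE = {
    "N": np.array([-1.35, 0.0, -0.35]),
    "CA": np.array([0.0, 0.0, 0.0]),
    "C": np.array([1.35, 0.0, 0.25]),
    "O": np.array([1.35, 0.0, 1.48]),
    "H": np.array([-1.35, 0.0, -1.35]),  # amide H, points along -z
}
_CB_OFFSET = 1.53  # Å, CA->CB along the outward normal
_RESIDUE_SPACING = 3.5  # Å along the strand


@dataclass(frozen=True)
class ZipperSpec:
    """Parameters of an ideal parallel in-register homo-zipper fibril."""

    sequence: str
    n_strands_per_sheet: int = 4
    rise: float = 4.8
    sheet_separation: float = 8.5
    start_residue: int = 69
    registration: str = "parallel_in_register"
    zipper_class: str = "homo"

    def __post_init__(self):
        if len(self.sequence) < 3:
            raise ValidationError("sequence must have at least 3 residues")
        if not (3.0 < self.rise < 6.5):
            raise ValidationError(f"rise {self.rise} outside (3.0, 6.5) Å")
        if self.n_strands_per_sheet < 1:
            raise ValidationError("n_strands_per_sheet must be >= 1")
        if self.registration != "parallel_in_register":
            raise ValidationError(
                "only parallel_in_register zippers are generated"
            )
        if self.zipper_class != "homo":
            raise ValidationError("only homo zippers are generated")
        for letter in self.sequence:
            side_chain_template(letter)  # raises on unknown residue


def build_strand_atoms(
    sequence: str,
    chain_id: str,
    start_residue: int,
    origin: np.ndarray,
    invert_xy: bool = False,
) -> list[AtomRecord]:
    """Atoms of one idealized extended strand.

    Side chains alternate across the sheet plane; residues with an even
    author index point toward +y (the mating sheet of sheet A). With
    ``invert_xy`` the strand is rotated 180° about z (sheet B orientation;
    chirality is preserved — all residues stay L).
    """
    atoms: list[AtomRecord] = []
    flip = np.array([-1.0, -1.0, 1.0]) if invert_xy else np.ones(3)
    for i, letter in enumerate(sequence):
        res_idx = start_residue + i
        res_name = AA1_TO_3[letter]
        base = np.array([i * _RESIDUE_SPACING, 0.0, 0.0])
        side = 1.0 if res_idx % 2 == 0 else -1.0

        def put(name, element, local):
            atoms.append(
                AtomRecord(
                    element=element,
                    name=name,
                    residue_name=res_name,
                    residue_index=res_idx,
                    chain_id=chain_id,
                    position=(base + local) * flip + origin,
                )
            )

        for name, off in _BACKBONE.items():
            put(name, "H" if name == "H" else name[0], off)
        template = side_chain_template(letter)
        if template is None:  # glycine
            continue
        cb = np.array([0.0, side * _CB_OFFSET, 0.0])
        put("CB", "C", cb)
        for name, element, (dx, dout, dz) in template:
            put(name, element, cb + np.array([dx, side * dout, dz]))
    return atoms


def build_ideal_zipper(spec: ZipperSpec) -> ZipperModel:
    """Build the ideal fibril lattice described by ``spec``.

    Sheet A strands sit at y = 0; sheet B is the same strand rotated 180°
    about the fibril axis, offset by half a residue spacing along the strand,
    half a rise along the axis, and ``sheet_separation`` across. The result
    has axis, rise and sheet assignment already set. Deterministic.
    """
    n_res = len(spec.sequence)
    chain_pool = iter(
        "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"
    )
    atoms: list[AtomRecord] = []
    sheet_a_ids: list[str] = []
    sheet_b_ids: list[str] = []

    for layer in range(spec.n_strands_per_sheet):
        cid = next(chain_pool)
        sheet_a_ids.append(cid)
        atoms.extend(
            build_strand_atoms(
                spec.sequence,
                cid,
                spec.start_residue,
                origin=np.array([0.0, 0.0, layer * spec.rise]),
            )
        )
    x_shift = (n_res - 1) * _RESIDUE_SPACING + _RESIDUE_SPACING / 2
    for layer in range(spec.n_strands_per_sheet):
        cid = next(chain_pool)
        sheet_b_ids.append(cid)
        atoms.extend(
            build_strand_atoms(
                spec.sequence,
                cid,
                spec.start_residue,
                origin=np.array(
                    [
                        x_shift,
                        spec.sheet_separation,
                        layer * spec.rise + spec.rise / 2,
                    ]
                ),
                invert_xy=True,
            )
        )

    span = (n_res + 2) * _RESIDUE_SPACING
    cell = (
        span + 20.0,
        spec.sheet_separation + 20.0,
        spec.rise,
        90.0,
        90.0,
        90.0,
    )
    return ZipperModel(
        atoms=tuple(atoms),
        unit_cell=cell,
        symmetry_ops=((np.eye(3), np.zeros(3)),),
        sheets=(tuple(sheet_a_ids), tuple(sheet_b_ids)),
        fibril_axis=np.array([0.0, 0.0, 1.0]),
        rise=spec.rise,
    )


# ---------------------------------------------------------------------------
# Synthetic assay data
# ---------------------------------------------------------------------------

def default_concentrations(
    n: int = 11, lo: float = 0.5, hi: float = 500.0
) -> tuple[float, ...]:
    """Log-spaced analyte concentration series, µM (default 0.5–500 µM)."""
    return tuple(float(c) for c in np.geomspace(lo, hi, n))


@dataclass(frozen=True)
class SynthIsothermSpec:
    """Ground truth for a synthetic steady-state binding isotherm.

    Responses follow the 1:1 model ``Req = C*Rmax/(KD + C) + RI`` with
    Gaussian noise of standard deviation ``noise_sd_frac * Rmax``.
    """

    kd_true: float  # µM
    rmax_true: float = 100.0  # response units
    ri_true: float = 2.0  # response units
    concentrations: tuple[float, ...] = field(
        default_factory=default_concentrations
    )
    noise_sd_frac: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.kd_true <= 0:
            raise ValidationError("kd_true must be positive")
        conc = np.asarray(self.concentrations, float)
        if conc.size < 5 or np.any(conc <= 0):
            raise ValidationError(
                "need >= 5 strictly positive concentrations"
            )
        if np.log10(conc.max() / conc.min()) < 2.0:
            raise ValidationError(
                "concentrations must span at least 2 log units"
            )
        if self.noise_sd_frac < 0:
            raise ValidationError("noise_sd_frac must be >= 0")


def synth_isotherm(spec: SynthIsothermSpec) -> BindingIsotherm:
    """Simulate one steady-state SPR isotherm; reproducible from the seed."""
    conc = np.sort(np.asarray(spec.concentrations, float))
    resp = conc * spec.rmax_true / (spec.kd_true + conc) + spec.ri_true
    if spec.noise_sd_frac > 0:
        rng = np.random.default_rng(spec.seed)
        resp = resp + rng.normal(
            0.0, spec.noise_sd_frac * spec.rmax_true, size=conc.shape
        )
    return BindingIsotherm(
        concentrations=tuple(conc),
        responses=tuple(float(r) for r in resp),
        analyte_label=f"synthetic(kd={spec.kd_true}µM,seed={spec.seed})",
    )


@dataclass(frozen=True)
class ThTCurveSpec:
    """Parameters of a synthetic control/inhibitor ThT curve pair.

    Curves are logistic in time — a fixture convenience emulating sigmoidal
    aggregation kinetics; the inhibitor curve's plateau is the control
    plateau divided by ``fold_reduction``.
    """

    control_plateau: float  # AU
    fold_reduction: float = 5.0
    lag: float = 10.0  # h, midpoint of the logistic
    rate: float = 0.5  # 1/h
    t_grid: tuple[float, ...] = tuple(float(t) for t in np.arange(0, 48.5, 0.5))
    noise_sd: float = 0.0  # AU
    seed: int = 0

    def __post_init__(self):
        if self.control_plateau <= 0:
            raise ValidationError("control_plateau must be positive")
        if self.fold_reduction < 1:
            raise ValidationError("fold_reduction must be >= 1")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


def synth_tht_curves(spec: ThTCurveSpec) -> tuple[ThTTrace, ThTTrace]:
    """Simulate a (control, inhibitor-treated) ThT fluorescence pair."""
    t = np.asarray(spec.t_grid, float)
    shape = 1.0 / (1.0 + np.exp(-spec.rate * (t - spec.lag)))
    rng = np.random.default_rng(spec.seed)
    traces = []
    for label, plateau in (
        ("control", spec.control_plateau),
        ("inhibitor", spec.control_plateau / spec.fold_reduction),
    ):
        f = plateau * shape
        if spec.noise_sd > 0:
            f = f + rng.normal(0.0, spec.noise_sd, size=t.shape)
        traces.append(
            ThTTrace(
                times=tuple(t),
                fluorescence=tuple(float(v) for v in f),
                condition_label=label,
            )
        )
    control, treated = traces
    return control, treated
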