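"""Atomic records, element radii and residue chemistry tables.

The vdW radii are a fixed united-atom element table (Chothia-style radii, as
used for hydrogen-less protein models), bundled so that clash and surface
calculations are deterministic and do not depend on any force-field
distribution. With these radii a canonical β-sheet N···O hydrogen bond
(~3.1 Å) sits just outside steric overlap (1.65 + 1.40 Å).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

from .errors import ValidationError

# United-atom element radii, Å. Unknown elements fall back to carbon.
VDW_RADII: dict[str, float] = {
    "H": 1.00,
    "C": 1.87,
    "N": 1.65,
    "O": 1.40,
    "S": 1.85,
    "P": 1.90,
    "SE": 1.90,
}
DEFAULT_VDW = 1.87


def vdw_radius(element: str) -> float:
    return VDW_RADII.get(element.upper(), DEFAULT_VDW)


AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}

# Side-chain formal charges at neutral pH. Termini are handled separately
# (synthetic peptides are assumed capped by default).
FORMAL_CHARGES: dict[str, int] = {"K": 1, "R": 1, "D": -1, "E": -1}


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a model, PDB-style.

    ``residue_index`` uses author numbering throughout (α-synuclein positions
    are 1-based, NACore spans 68–78).
    """

    element: str
    name: str
    residue_name: str
    residue_index: int
    chain_id: str
    position: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValidationError(
                f"atom {self.name}/{self.residue_name}{self.residue_index}: "
                "position must be a finite 3-vector"
            )
        object.__setattr__(self, "position", pos)
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValidationError(
                f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]"
            )

    @property
    def vdw(self) -> float:
        return vdw_radius(self.element)

    def moved(self, new_position: np.ndarray) -> "AtomRecord":
        return replace(self, position=np.asarray(new_position, float))


def coords(atoms: Iterable[AtomRecord]) -> np.ndarray:
    """Coordinate matrix (n, 3) of an atom collection."""
    arr = np.array([a.position for a in atoms], dtype=float)
    return arr.reshape(-1, 3)


def radii(atoms: Iterable[AtomRecord]) -> np.ndarray:
    return np.array([a.vdw for a in atoms], dtype=float)


BACKBONE_NAMES = ("N", "CA", "C", "O")

# ---------------------------------------------------------------------------
# Schematic side-chain templates for the ideal-zipper builder.
#
# Local frame per residue: x = strand direction, "out" = direction away from
# the sheet plane toward the mating sheet (sign alternates along the strand),
# z = fibril axis. Offsets are from CB and approximate real bond geometry
# closely enough for ordinal interface scoring; they are NOT crystallographic.
# Each entry: (atom name, element, (dx, d_out, dz)).
# ---------------------------------------------------------------------------
_SC = {
    "A": [],
    "G": None,  # no CB
    "S": [("OG", "O", (0.45, 1.25, 0.30))],
    "C": [("SG", "S", (0.50, 1.45, 0.30))],
    "V": [("CG1", "C", (1.20, 0.95, 0.15)), ("CG2", "C", (-1.20, 0.95, -0.15))],
    "T": [("OG1", "O", (1.20, 0.95, 0.15)), ("CG2", "C", (-1.20, 0.95, -0.15))],
    "I": [
        ("CG1", "C", (0.60, 1.30, 0.20)),
        ("CG2", "C", (-1.20, 0.95, -0.15)),
        ("CD1", "C", (0.30, 2.70, 0.30)),
    ],
    "L": [
        ("CG", "C", (0.45, 1.35, 0.15)),
        ("CD1", "C", (1.60, 2.20, 0.25)),
        ("CD2", "C", (-0.70, 2.25, 0.05)),
    ],
    "M": [
        ("CG", "C", (0.55, 1.30, 0.15)),
        ("SD", "S", (-0.30, 2.55, 0.00)),
        ("CE", "C", (0.55, 3.90, 0.15)),
    ],
    "F": [
        ("CG", "C", (0.00, 1.45, 0.10)),
        ("CD1", "C", (1.15, 2.20, 0.10)),
        ("CD2", "C", (-1.15, 2.20, 0.10)),
        ("CE1", "C", (1.15, 3.55, 0.10)),
        ("CE2", "C", (-1.15, 3.55, 0.10)),
        ("CZ", "C", (0.00, 4.30, 0.10)),
    ],
    "Y": [
        ("CG", "C", (0.00, 1.45, 0.10)),
        ("CD1", "C", (1.15, 2.20, 0.10)),
        ("CD2", "C", (-1.15, 2.20, 0.10)),
        ("CE1", "C", (1.15, 3.55, 0.10)),
        ("CE2", "C", (-1.15, 3.55, 0.10)),
        ("CZ", "C", (0.00, 4.30, 0.10)),
        ("OH", "O", (0.00, 5.65, 0.10)),
    ],
    "W": [
        ("CG", "C", (0.00, 1.45, 0.10)),
        ("CD1", "C", (1.15, 2.15, 0.10)),
        ("CD2", "C", (-1.05, 2.25, 0.10)),
        ("NE1", "N", (1.05, 3.45, 0.10)),
        ("CE2", "C", (-0.25, 3.55, 0.10)),
        ("CE3", "C", (-2.35, 2.00, 0.10)),
        ("CZ2", "C", (-1.00, 4.70, 0.10)),
        ("CZ3", "C", (-3.10, 3.15, 0.10)),
        ("CH2", "C", (-2.40, 4.50, 0.10)),
    ],
    "D": [
        ("CG", "C", (0.40, 1.35, 0.10)),
        ("OD1", "O", (1.50, 1.95, 0.15)),
        ("OD2", "O", (-0.65, 2.05, 0.05)),
    ],
    "N": [
        ("CG", "C", (0.40, 1.35, 0.10)),
        ("OD1", "O", (1.50, 1.95, 0.15)),
        ("ND2", "N", (-0.65, 2.05, 0.05)),
    ],
    "E": [
        ("CG", "C", (0.45, 1.30, 0.10)),
        ("CD", "C", (-0.25, 2.55, 0.00)),
        ("OE1", "O", (0.45, 3.60, 0.10)),
        ("OE2", "O", (-1.45, 2.80, -0.10)),
    ],
    "Q": [
        ("CG", "C", (0.45, 1.30, 0.10)),
        ("CD", "C", (-0.25, 2.55, 0.00)),
        ("OE1", "O", (0.45, 3.60, 0.10)),
        ("NE2", "N", (-1.45, 2.80, -0.10)),
    ],
    "H": [
        ("CG", "C", (0.00, 1.45, 0.10)),
        ("ND1", "N", (1.15, 2.25, 0.10)),
        ("CD2", "C", (-1.10, 2.30, 0.10)),
        ("CE1", "C", (0.70, 3.50, 0.10)),
        ("NE2", "N", (-0.65, 3.55, 0.10)),
    ],
    "K": [
        ("CG", "C", (0.55, 1.30, 0.15)),
        ("CD", "C", (-0.30, 2.45, 0.00)),
        ("CE", "C", (0.55, 3.60, 0.15)),
        ("NZ", "N", (-0.25, 4.75, 0.00)),
    ],
    "R": [
        ("CG", "C", (0.55, 1.30, 0.15)),
        ("CD", "C", (-0.30, 2.45, 0.00)),
        ("NE", "N", (0.55, 3.60, 0.15)),
        ("CZ", "C", (-0.10, 4.75, 0.05)),
        ("NH1", "N", (1.00, 5.65, 0.15)),
        ("NH2", "N", (-1.30, 5.10, -0.05)),
    ],
    "P": [("CG", "C", (0.75, 1.25, 0.20)), ("CD", "C", (-0.45, 1.90, 0.00))],
}


def side_chain_template(one_letter: str):
    """Heavy side-chain atoms beyond CB for ``one_letter`` (None for Gly)."""
    try:
        return _SC[one_letter]
    except KeyError:
        raise ValidationError(f"unknown residue letter {one_letter!r}") from None
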