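"""Steric-zipper fibril lattices: parsing, symmetry expansion, tip extraction.

An amyloid steric zipper is a pair of tightly mated β-sheets; each sheet is a
stack of short peptide strands related by a ~4.8 Å translation along the
fibril axis. Capping inhibitors target the two growth ends ("top" and
"bottom") of such a protofilament, so the structural work here is: read a
crystal structure, expand its symmetry into a finite lattice, find the fibril
axis and rise, and pull out the two tip interfaces.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .atoms import AA3_TO_1, AtomRecord, BACKBONE_NAMES, coords
from .errors import (
    AmbiguousAxisError,
    AxisDetectionError,
    EmptyModelError,
    InsufficientContextError,
    ParseError,
    ValidationError,
)
from .geometry import rmsd

logger = logging.getLogger(__name__)

#: Two inter-strand translations are "the same" if they differ by less than
#: this many Å componentwise-combined; the crystallographic rise (~4.8 Å)
#: dominates coordinate noise by an order of magnitude.
TRANSLATION_TOL = 0.2
#: Plausible strand-stacking rise range, Å.
RISE_RANGE = (3.0, 6.5)
#: Peptide-bond C–N distance above which a chain is split into two strands.
CHAIN_BREAK_CUTOFF = 2.5

_CHAIN_ID_POOL = (
    "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"
)


@dataclass(frozen=True)
class Strand:
    """One β-strand: a contiguous stretch of residues of a single chain."""

    strand_id: str
    chain_id: str
    atom_indices: tuple[int, ...]
    residue_range: tuple[int, int]

    def __len__(self) -> int:
        return self.residue_range[1] - self.residue_range[0] + 1


@dataclass(frozen=True)
class ZipperModel:
    """Atomic model of a steric-zipper protofilament.

    ``unit_cell`` is (a, b, c, alpha, beta, gamma) in Å/degrees;
    ``symmetry_ops`` are fractional (R, t) pairs. ``fibril_axis`` / ``rise`` /
    ``sheets`` are unset until :func:`detect_fibril_axis` /
    :func:`assign_geometry` run.
    """

    atoms: tuple[AtomRecord, ...]
    unit_cell: tuple[float, float, float, float, float, float] | None = None
    symmetry_ops: tuple[tuple[np.ndarray, np.ndarray], ...] = ()
    sheets: tuple[tuple[str, ...], tuple[str, ...]] | None = None
    fibril_axis: np.ndarray | None = None
    rise: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "atoms", tuple(self.atoms))
        if self.fibril_axis is not None:
            ax = np.asarray(self.fibril_axis, float)
            n = np.linalg.norm(ax)
            if not np.isclose(n, 1.0, atol=1e-6):
                ax = ax / n
            object.__setattr__(self, "fibril_axis", ax)
        if self.rise is not None and self.rise <= 0:
            raise ValidationError("rise must be positive")

    # -- strand bookkeeping -------------------------------------------------

    @property
    def strands(self) -> tuple[Strand, ...]:
        return _find_strands(self.atoms)

    def strand(self, strand_id: str) -> Strand:
        for s in self.strands:
            if s.strand_id == strand_id:
                return s
        raise KeyError(f"no strand {strand_id!r}")

    def strand_atoms(self, strand_id: str) -> list[AtomRecord]:
        return [self.atoms[i] for i in self.strand(strand_id).atom_indices]

    def strand_sequence(self, strand_id: str) -> str:
        seen: dict[int, str] = {}
        for a in self.strand_atoms(strand_id):
            seen.setdefault(a.residue_index, AA3_TO_1.get(a.residue_name, "X"))
        return "".join(seen[i] for i in sorted(seen))

    def chain_ids(self) -> list[str]:
        out: list[str] = []
        for a in self.atoms:
            if a.chain_id not in out:
                out.append(a.chain_id)
        return out


@dataclass(frozen=True)
class TipInterface:
    """One growth end of the protofilament and its exposed surfaces.

    ``template_strand`` is the extreme strand on this face; a capping peptide
    is threaded onto its backbone shifted one rise outward.
    ``context_atoms`` are the strands of the template's own sheet directly
    below the tip; ``mating_sheet_atoms`` the adjacent strands of the opposing
    sheet.
    """

    face: str  # "top" | "bottom"
    template_strand: str
    context_atoms: tuple[AtomRecord, ...]
    mating_sheet_atoms: tuple[AtomRecord, ...]
    template_atoms: tuple[AtomRecord, ...]
    axis: np.ndarray
    rise: float
    context_strand_ids: tuple[str, ...] = ()
    mating_strand_ids: tuple[str, ...] = ()

    @property
    def outward(self) -> np.ndarray:
        """Unit vector pointing out of the fibril on this face."""
        sign = 1.0 if self.face == "top" else -1.0
        return sign * np.asarray(self.axis, float)

    @property
    def template_span(self) -> tuple[int, int]:
        idx = [a.residue_index for a in self.template_atoms]
        return (min(idx), max(idx))

    @property
    def template_sequence(self) -> str:
        seen: dict[int, str] = {}
        for a in self.template_atoms:
            seen.setdefault(a.residue_index, AA3_TO_1.get(a.residue_name, "X"))
        return "".join(seen[i] for i in sorted(seen))


# ---------------------------------------------------------------------------
# Strand detection
# ---------------------------------------------------------------------------

def _find_strands(atoms: Sequence[AtomRecord]) -> tuple[Strand, ...]:
    """Group atoms into strands: one chain = one strand, except chains with a
    peptide-bond break (C(i)–N(i+1) > 2.5 Å), which are split there."""
    by_chain: dict[str, list[int]] = {}
    for i, a in enumerate(atoms):
        by_chain.setdefault(a.chain_id, []).append(i)

    strands: list[Strand] = []
    for chain_id, idxs in by_chain.items():
        # group by residue, in author order of appearance
        residues: dict[int, list[int]] = {}
        for i in idxs:
            residues.setdefault(atoms[i].residue_index, []).append(i)
        res_order = sorted(residues)
        # find break points
        segments: list[list[int]] = [[res_order[0]]] if res_order else []
        for prev, cur in zip(res_order, res_order[1:]):
            broken = cur != prev + 1
            if not broken:
                c_pos = _atom_pos(atoms, residues[prev], "C")
                n_pos = _atom_pos(atoms, residues[cur], "N")
                if c_pos is not None and n_pos is not None:
                    broken = np.linalg.norm(c_pos - n_pos) > CHAIN_BREAK_CUTOFF
            if broken:
                segments.append([cur])
            else:
                segments[-1].append(cur)
        for k, seg in enumerate(segments):
            sid = chain_id if len(segments) == 1 else f"{chain_id}.{k + 1}"
            atom_idx = tuple(i for r in seg for i in residues[r])
            strands.append(Strand(sid, chain_id, atom_idx, (seg[0], seg[-1])))
    return tuple(strands)


def _atom_pos(atoms, idxs, name):
    for i in idxs:
        if atoms[i].name == name:
            return atoms[i].position
    return None


# ---------------------------------------------------------------------------
# Parsing (gemmi-backed: PDB and mmCIF)
# ---------------------------------------------------------------------------

def parse_zipper(path: str | Path) -> ZipperModel:
    """Read a steric-zipper crystal structure (PDB or mmCIF).

    Keeps all protein ATOM/HETATM coordinates, the unit cell and the
    space-group symmetry operators. Alternate locations are resolved by
    keeping the first conformer (altloc 'A' by PDB convention); the choice is
    logged. Waters and other non-amino-acid heterogens are dropped.
    """
    import gemmi

    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse {path.name}: {exc}") from exc

    if st.input_format in (gemmi.CoorFormat.Unknown,):
        raise ParseError(f"{path.name}: unrecognized structure format")

    st.setup_entities()
    st.remove_alternative_conformations()
    logger.info("altloc policy: keeping first conformer (altloc 'A')")

    records: list[AtomRecord] = []
    if len(st) == 0:
        raise EmptyModelError(f"{path.name}: structure has no models")
    model = st[0]
    for chain in model:
        for res in chain:
            info = gemmi.find_tabulated_residue(res.name)
            if info is None or not info.is_amino_acid():
                continue
            for atom in res:
                records.append(
                    AtomRecord(
                        element=atom.element.name,
                        name=atom.name,
                        residue_name=res.name,
                        residue_index=res.seqid.num,
                        chain_id=chain.name,
                        position=np.array(
                            [atom.pos.x, atom.pos.y, atom.pos.z]
                        ),
                        occupancy=min(max(atom.occ, 0.0), 1.0),
                        b_factor=atom.b_iso,
                    )
                )
    if not records:
        raise EmptyModelError(f"{path.name}: no protein atoms found")

    cell = None
    if st.cell.volume > 1.0:
        cell = (
            st.cell.a, st.cell.b, st.cell.c,
            st.cell.alpha, st.cell.beta, st.cell.gamma,
        )

    ops: list[tuple[np.ndarray, np.ndarray]] = []
    sg = st.find_spacegroup()
    if sg is not None:
        for op in sg.operations():
            rot = np.array(op.rot, dtype=float) / op.DEN
            tran = np.array(op.tran, dtype=float) / op.DEN
            ops.append((rot, tran))
    else:
        ops.append((np.eye(3), np.zeros(3)))

    return ZipperModel(atoms=tuple(records), unit_cell=cell,
                       symmetry_ops=tuple(ops))


# ---------------------------------------------------------------------------
# Symmetry expansion
# ---------------------------------------------------------------------------

def _orthogonalization(cell) -> np.ndarray:
    """Standard fractional→Cartesian matrix for a unit cell."""
    a, b, c, al, be, ga = cell
    al, be, ga = np.deg2rad([al, be, ga])
    cos_al, cos_be, cos_ga = np.cos([al, be, ga])
    sin_ga = np.sin(ga)
    v = np.sqrt(
        1 - cos_al**2 - cos_be**2 - cos_ga**2 + 2 * cos_al * cos_be * cos_ga
    )
    return np.array(
        [
            [a, b * cos_ga, c * cos_be],
            [0, b * sin_ga, c * (cos_al - cos_be * cos_ga) / sin_ga],
            [0, 0, c * v / sin_ga],
        ]
    )


def _cartesian_ops(model: ZipperModel) -> list[tuple[np.ndarray, np.ndarray]]:
    if model.unit_cell is None:
        return [(np.asarray(r, float), np.asarray(t, float))
                for r, t in model.symmetry_ops]
    m = _orthogonalization(model.unit_cell)
    m_inv = np.linalg.inv(m)
    out = []
    for r, t in model.symmetry_ops:
        out.append((m @ np.asarray(r, float) @ m_inv, m @ np.asarray(t, float)))
    return out


def _stacking_generator(model: ZipperModel) -> tuple[np.ndarray, np.ndarray]:
    """Pick the symmetry/lattice operation that stacks strands along the
    fibril: a (near-)pure translation with a 3–6.5 Å Cartesian component."""
    lo, hi = RISE_RANGE
    candidates: list[tuple[float, np.ndarray, np.ndarray]] = []

    for rot, t in _cartesian_ops(model):
        if np.allclose(rot, np.eye(3), atol=1e-6):
            norm = float(np.linalg.norm(t))
            if lo < norm < hi:
                candidates.append((abs(norm - 4.8), rot, t))

    if model.unit_cell is not None:
        m = _orthogonalization(model.unit_cell)
        for k in range(3):
            vec = m[:, k]
            norm = float(np.linalg.norm(vec))
            if lo < norm < hi:
                candidates.append((abs(norm - 4.8), np.eye(3), vec))

    if not candidates:
        # screw axes: translation component along the rotation axis
        for rot, t in _cartesian_ops(model):
            if np.allclose(rot, np.eye(3), atol=1e-6):
                continue
            w, v = np.linalg.eig(rot)
            axis_cols = np.isclose(w, 1.0, atol=1e-6)
            if not axis_cols.any():
                continue
            axis = np.real(v[:, axis_cols][:, 0])
            axis /= np.linalg.norm(axis)
            tau = abs(float(t @ axis))
            if 2.0 < tau < hi:
                candidates.append((abs(tau - 4.8), rot, t))

    if not candidates:
        raise AxisDetectionError(
            "no symmetry or lattice operation with a ~4–5 Å translation "
            "component found; supply the fibril axis and rise manually"
        )
    candidates.sort(key=lambda c: c[0])
    _, rot, t = candidates[0]
    return rot, t


def expand_symmetry(model: ZipperModel, n_layers: int) -> ZipperModel:
    """Stack ``n_layers`` symmetry copies of the asymmetric unit along the
    fibril direction. Layer 0 is the input, unmoved; generated chains get
    fresh single-character identifiers."""
    if n_layers < 1:
        raise ValidationError("n_layers must be >= 1")
    if n_layers == 1:
        return model

    rot, t = _stacking_generator(model)

    used = set(model.chain_ids())
    pool = iter(c for c in _CHAIN_ID_POOL if c not in used)

    new_atoms: list[AtomRecord] = list(model.atoms)
    chain_map_cache: dict[tuple[int, str], str] = {}
    for k in range(1, n_layers):
        # op applied k times
        rk = np.linalg.matrix_power(rot, k)
        tk = np.zeros(3)
        for j in range(k):
            tk = rot @ tk + t
        for a in model.atoms:
            key = (k, a.chain_id)
            if key not in chain_map_cache:
                try:
                    chain_map_cache[key] = next(pool)
                except StopIteration:
                    raise ValidationError(
                        "chain identifier pool exhausted; reduce n_layers"
                    ) from None
            new_atoms.append(
                replace(
                    a,
                    chain_id=chain_map_cache[key],
                    position=rk @ a.position + tk,
                )
            )
    return replace(model, atoms=tuple(new_atoms), sheets=None,
                   fibril_axis=None, rise=None)


# ---------------------------------------------------------------------------
# Axis detection and sheet assignment
# ---------------------------------------------------------------------------

def _strand_backbone_coords(model: ZipperModel, strand: Strand) -> np.ndarray:
    keyed = {}
    for i in strand.atom_indices:
        a = model.atoms[i]
        if a.name in BACKBONE_NAMES:
            keyed[(a.residue_index - strand.residue_range[0], a.name)] = (
                a.position
            )
    return np.array([keyed[k] for k in sorted(keyed)])


def detect_fibril_axis(model: ZipperModel) -> tuple[np.ndarray, float]:
    """Find the fibril axis and rise.

    Consecutive strands of a sheet must be related by a pure translation;
    candidate translations are pairwise strand offsets of 3–6.5 Å that
    superpose the strand backbones, clustered with a 0.2 Å / 5° tolerance.
    The axis sign is canonicalized so that its largest-magnitude component is
    positive ("top" = +axis).
    """
    strands = model.strands
    if len(strands) < 2:
        raise AmbiguousAxisError(
            "at least two strands are needed to detect the fibril axis"
        )
    lo, hi = RISE_RANGE
    vectors: list[np.ndarray] = []
    bb = {s.strand_id: _strand_backbone_coords(model, s) for s in strands}
    for i, si in enumerate(strands):
        for sj in strands[i + 1:]:
            if len(si) != len(sj) or bb[si.strand_id].shape != bb[sj.strand_id].shape:
                continue
            delta = bb[sj.strand_id].mean(axis=0) - bb[si.strand_id].mean(axis=0)
            norm = np.linalg.norm(delta)
            if not (lo < norm < hi):
                continue
            if rmsd(bb[si.strand_id] + delta, bb[sj.strand_id]) > 0.5:
                continue
            # canonical sign: largest-|component| positive
            k = int(np.argmax(np.abs(delta)))
            vectors.append(delta if delta[k] > 0 else -delta)

    if not vectors:
        raise AmbiguousAxisError(
            "no pair of strands is related by a 3–6.5 Å pure translation"
        )

    # cluster within TRANSLATION_TOL
    clusters: list[list[np.ndarray]] = []
    for v in vectors:
        for cl in clusters:
            if np.linalg.norm(v - cl[0]) < TRANSLATION_TOL:
                cl.append(v)
                break
        else:
            clusters.append([v])
    clusters.sort(key=len, reverse=True)
    best = np.mean(clusters[0], axis=0)
    if len(clusters) > 1 and len(clusters[1]) == len(clusters[0]):
        other = np.mean(clusters[1], axis=0)
        angle = np.degrees(
            np.arccos(
                np.clip(
                    abs(best @ other)
                    / (np.linalg.norm(best) * np.linalg.norm(other)),
                    -1, 1,
                )
            )
        )
        if angle > 5.0:
            raise AmbiguousAxisError(
                "two equally supported, inconsistent stacking translations"
            )
    rise = float(np.linalg.norm(best))
    return best / rise, rise


def assign_geometry(model: ZipperModel) -> ZipperModel:
    """Detect axis/rise and partition strands into the two β-sheets.

    Strands linked by a ±rise·axis translation belong to one sheet; a steric
    zipper must yield exactly two sheets.
    """
    axis, rise = detect_fibril_axis(model)
    strands = model.strands
    bb = {s.strand_id: _strand_backbone_coords(model, s) for s in strands}
    step = rise * axis

    parent = {s.strand_id: s.strand_id for s in strands}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, si in enumerate(strands):
        for sj in strands[i + 1:]:
            if bb[si.strand_id].shape != bb[sj.strand_id].shape:
                continue
            delta = bb[sj.strand_id].mean(axis=0) - bb[si.strand_id].mean(axis=0)
            if (
                np.linalg.norm(delta - step) < TRANSLATION_TOL
                or np.linalg.norm(delta + step) < TRANSLATION_TOL
            ):
                parent[find(si.strand_id)] = find(sj.strand_id)

    comps: dict[str, list[str]] = {}
    for s in strands:
        comps.setdefault(find(s.strand_id), []).append(s.strand_id)
    if len(comps) != 2:
        raise ValidationError(
            f"expected exactly 2 β-sheets, found {len(comps)} strand stacks"
        )
    sheet_a, sheet_b = sorted(comps.values(), key=lambda ids: sorted(ids)[0])
    return replace(
        model,
        sheets=(tuple(sheet_a), tuple(sheet_b)),
        fibril_axis=axis,
        rise=rise,
    )


# ---------------------------------------------------------------------------
# Tip extraction
# ---------------------------------------------------------------------------

def extract_tips(
    model: ZipperModel,
    context_layers: int = 4,
    mating_cutoff: float = 12.0,
) -> tuple[TipInterface, TipInterface]:
    """Extract the top and bottom tip interfaces of the fibril.

    The template strand of each face is the strand with the extreme mean
    projection onto the fibril axis. ``context_layers`` strands of the
    template's sheet (template included) form the binding context;
    ``mating_sheet_atoms`` are atoms of the opposing sheet within
    ``mating_cutoff`` Å of the capping site.
    """
    if context_layers < 1:
        raise ValidationError("context_layers must be >= 1")
    if model.fibril_axis is None or model.rise is None or model.sheets is None:
        model = assign_geometry(model)
    axis = model.fibril_axis
    rise = model.rise
    strands = {s.strand_id: s for s in model.strands}

    per_sheet = min(len(sh) for sh in model.sheets)
    if per_sheet < context_layers:
        raise InsufficientContextError(
            f"{context_layers} context layers requested but sheets have only "
            f"{per_sheet} strands"
        )

    def proj(sid: str) -> float:
        return float(
            np.mean([model.atoms[i].position @ axis
                     for i in strands[sid].atom_indices])
        )

    tips = []
    for face, pick in (("top", max), ("bottom", min)):
        template_id = pick(strands, key=proj)
        sheet_idx = 0 if template_id in model.sheets[0] else 1
        own_ids = sorted(
            model.sheets[sheet_idx], key=proj, reverse=(face == "top")
        )[:context_layers]
        context = [
            model.atoms[i]
            for sid in own_ids
            for i in strands[sid].atom_indices
        ]
        # capping site: template backbone shifted one rise outward
        sign = 1.0 if face == "top" else -1.0
        site = coords(
            [model.atoms[i] for i in strands[template_id].atom_indices]
        ) + sign * rise * axis
        mating_ids = []
        other_sheet = model.sheets[1 - sheet_idx]
        for sid in other_sheet:
            pts = coords([model.atoms[i] for i in strands[sid].atom_indices])
            dmin = np.min(
                np.linalg.norm(
                    pts[:, None, :] - site[None, :, :], axis=2
                )
            )
            if dmin <= mating_cutoff:
                mating_ids.append(sid)
        mating = [
            model.atoms[i]
            for sid in mating_ids
            for i in strands[sid].atom_indices
        ]
        tips.append(
            TipInterface(
                face=face,
                template_strand=template_id,
                context_atoms=tuple(context),
                mating_sheet_atoms=tuple(mating),
                template_atoms=tuple(
                    model.atoms[i]
                    for i in strands[template_id].atom_indices
                ),
                axis=axis,
                rise=rise,
                context_strand_ids=tuple(own_ids),
                mating_strand_ids=tuple(mating_ids),
            )
        )
    top, bottom = tips
    return top, bottom


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

def write_pdb(atoms_or_model, path: str | Path, unit_cell=None) -> None:
    """Write atoms as a fixed-column PDB file (CRYST1 included when a cell is
    known)."""
    if isinstance(atoms_or_model, ZipperModel):
        atoms = atoms_or_model.atoms
        unit_cell = unit_cell or atoms_or_model.unit_cell
    else:
        atoms = list(atoms_or_model)
    lines = []
    if unit_cell is not None:
        a, b, c, al, be, ga = unit_cell
        lines.append(
            f"CRYST1{a:9.3f}{b:9.3f}{c:9.3f}{al:7.2f}{be:7.2f}{ga:7.2f} P 1"
        )
    serial = 0
    prev_chain = None
    for atom in atoms:
        if prev_chain is not None and atom.chain_id != prev_chain:
            lines.append("TER")
        prev_chain = atom.chain_id
        serial += 1
        name = atom.name
        # PDB atom-name column convention
        pname = f" {name:<3s}" if len(name) < 4 and len(atom.element) == 1 else f"{name:<4s}"
        x, y, z = atom.position
        lines.append(
            f"ATOM  {serial % 100000:5d} {pname}{' '}{atom.residue_name:>3s} "
            f"{atom.chain_id[:1]}{atom.residue_index:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{atom.b_factor:6.2f}"
            f"          {atom.element:>2s}"
        )
    lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def tip_metadata(top: TipInterface, bottom: TipInterface) -> dict:
    """JSON-serializable description of the two tips."""
    def one(tip: TipInterface) -> dict:
        lo, hi = tip.template_span
        return {
            "face": tip.face,
            "template_strand": tip.template_strand,
            "template_sequence": tip.template_sequence,
            "residue_range": [lo, hi],
            "context_strands": list(tip.context_strand_ids),
            "mating_strands": list(tip.mating_strand_ids),
            "rise": tip.rise,
            "axis": [float(v) for v in tip.axis],
        }

    return {"top": one(top), "bottom": one(bottom)}


def write_tip_metadata(top: TipInterface, bottom: TipInterface,
                       path: str | Path) -> None:
    Path(path).write_text(json.dumps(tip_metadata(top, bottom), indent=2))
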