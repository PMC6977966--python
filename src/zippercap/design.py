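"""Threading, rigid/rotamer pose optimization and iterative redesign.

A candidate peptide is threaded onto a tip: its backbone copies the tip
template strand shifted one rise outward (the position the next incoming
monomer would occupy), and its side chains are rebuilt on idealized
templates in the local strand frame. Optimization is deterministic greedy
coordinate descent — small rigid-body perturbations plus discrete χ1 rotamer
swaps — and sequence design is the fix-and-redesign loop: scan single-point
substitutions, fix the best one, repeat on the remaining positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .atoms import AA1_TO_3, AtomRecord, side_chain_template
from .candidates import CandidateInhibitor
from .errors import ThreadingError, ValidationError
from .geometry import rotation_matrix
from .zipper import TipInterface, ZipperModel, extract_tips

logger = logging.getLogger(__name__)

POSE_CHAIN_ID = "p"


@dataclass(frozen=True)
class DesignPose:
    """A candidate placed at one tip."""

    candidate: CandidateInhibitor
    face: str
    atoms: tuple[AtomRecord, ...]
    rigid_rotation: np.ndarray = field(
        default_factory=lambda: np.eye(3)
    )
    rigid_translation: np.ndarray = field(
        default_factory=lambda: np.zeros(3)
    )
    optimization_failed: bool = False

    def __post_init__(self):
        object.__setattr__(self, "atoms", tuple(self.atoms))

    @property
    def heavy_atoms(self) -> tuple[AtomRecord, ...]:
        return tuple(a for a in self.atoms if a.element != "H")

    def residues(self) -> dict[int, list[AtomRecord]]:
        out: dict[int, list[AtomRecord]] = {}
        for a in self.atoms:
            out.setdefault(a.residue_index, []).append(a)
        return out

    def transformed(self, rot: np.ndarray, trans: np.ndarray) -> "DesignPose":
        """Apply a rigid motion about the pose centroid."""
        center = np.mean([a.position for a in self.atoms], axis=0)
        atoms = tuple(
            a.moved(rot @ (a.position - center) + center + trans)
            for a in self.atoms
        )
        return replace(
            self,
            atoms=atoms,
            rigid_rotation=rot @ self.rigid_rotation,
            rigid_translation=self.rigid_translation + trans,
        )


# ---------------------------------------------------------------------------
# Threading
# ---------------------------------------------------------------------------

def _template_residues(tip: TipInterface) -> dict[int, dict[str, AtomRecord]]:
    res: dict[int, dict[str, AtomRecord]] = {}
    for a in tip.template_atoms:
        res.setdefault(a.residue_index, {})[a.name] = a
    return res


def _local_frames(
    tip: TipInterface, residues: dict[int, dict[str, AtomRecord]]
) -> dict[int, tuple[np.ndarray, np.ndarray, np.ndarray, float]]:
    """Per-residue (ex, ey, ez, outward_sign) strand frames.

    ex follows the strand direction (CA(i)→CA(i+1)), ez is the fibril axis,
    ey completes the frame. The side-chain direction sign comes from the
    template's own CB when present, with parity alternation filling in for
    glycines.
    """
    order = sorted(residues)
    ca = {i: residues[i]["CA"].position for i in order if "CA" in residues[i]}
    ez = np.asarray(tip.axis, float)
    frames = {}
    signs: dict[int, float] = {}
    for i in order:
        nxt = i + 1 if (i + 1) in ca else i
        prv = i - 1 if (i - 1) in ca else i
        if nxt == prv:
            raise ThreadingError("template strand too short for a frame")
        ex = ca[nxt] - ca[prv]
        ex = ex - (ex @ ez) * ez
        ex /= np.linalg.norm(ex)
        ey = np.cross(ez, ex)
        ey /= np.linalg.norm(ey)
        frames[i] = (ex, ey, ez)
        if "CB" in residues[i]:
            signs[i] = float(
                np.sign((residues[i]["CB"].position - ca[i]) @ ey) or 1.0
            )
    # parity fill-in for residues without CB (Gly): β-strands alternate sides
    ref = next(iter(signs.items()), None)
    out = {}
    for i in order:
        if i in signs:
            sign = signs[i]
        elif ref is not None:
            ref_i, ref_sign = ref
            sign = ref_sign * (1.0 if (i - ref_i) % 2 == 0 else -1.0)
        else:
            sign = 1.0 if i % 2 == 0 else -1.0
        ex, ey, ez_ = frames[i]
        out[i] = (ex, ey, ez_, sign)
    return out


def thread_sequence(
    tip: TipInterface, candidate: CandidateInhibitor
) -> DesignPose:
    """Thread a candidate onto a tip.

    The pose backbone is the template strand backbone translated one rise
    outward; side chains are rebuilt for the candidate sequence at idealized
    geometry. Backbone N-methylation replaces the amide hydrogen with a
    methyl carbon (named ``CN``), deleting the hydrogen-bond donor.
    """
    residues = _template_residues(tip)
    t_lo, t_hi = min(residues), max(residues)
    c_lo, c_hi = candidate.span
    if not (t_lo <= c_lo and c_hi <= t_hi):
        raise ThreadingError(
            f"candidate span {c_lo}–{c_hi} does not fit the template span "
            f"{t_lo}–{t_hi}"
        )
    frames = _local_frames(tip, residues)
    shift = tip.rise * tip.outward
    sequence = candidate.effective_sequence
    methylated = set(candidate.n_methylated_positions)

    atoms: list[AtomRecord] = []
    for offset, letter in enumerate(sequence):
        pos = c_lo + offset
        template = residues[pos]
        for name in ("N", "CA", "C", "O"):
            if name not in template:
                raise ThreadingError(
                    f"template residue {pos} lacks backbone atom {name}"
                )
        res_name = AA1_TO_3[letter]

        def put(name, element, position):
            atoms.append(
                AtomRecord(
                    element=element,
                    name=name,
                    residue_name=res_name,
                    residue_index=pos,
                    chain_id=POSE_CHAIN_ID,
                    position=position,
                )
            )

        n_pos = template["N"].position + shift
        for name in ("N", "CA", "C", "O"):
            put(name, name[0], template[name].position + shift)
        # amide hydrogen / N-methyl
        if "H" in template:
            h_dir = template["H"].position - template["N"].position
            h_dir = h_dir / np.linalg.norm(h_dir)
        else:
            co = template["O"].position - template["C"].position
            h_dir = -co / np.linalg.norm(co)
        if pos in methylated:
            put("CN", "C", n_pos + 1.45 * h_dir)
        elif letter != "P":
            put("H", "H", n_pos + 1.0 * h_dir)

        sc = side_chain_template(letter)
        if sc is None:  # glycine
            continue
        ex, ey, ez, sign = frames[pos]
        ca_pos = template["CA"].position + shift
        cb = ca_pos + sign * 1.53 * ey
        put("CB", "C", cb)
        for name, element, (dx, dout, dz) in sc:
            put(name, element, cb + dx * ex + sign * dout * ey + dz * ez)

    return DesignPose(candidate=candidate, face=tip.face, atoms=tuple(atoms))


# ---------------------------------------------------------------------------
# Rigid/rotamer optimization
# ---------------------------------------------------------------------------

def _rotamer_variants(pose: DesignPose, residue_index: int) -> list[DesignPose]:
    """χ1 rotamer swaps: rotate side-chain atoms beyond CB about CA–CB."""
    by_res = pose.residues()
    atoms = by_res.get(residue_index, [])
    named = {a.name: a for a in atoms}
    if "CB" not in named or "CA" not in named:
        return []
    side = [
        a for a in atoms
        if a.name not in ("N", "CA", "C", "O", "H", "CN", "CB")
    ]
    if not side:
        return []
    axis = named["CB"].position - named["CA"].position
    variants = []
    for angle in (120.0, 240.0):
        rot = rotation_matrix(axis, angle)
        moved = {
            id(a): a.moved(
                rot @ (a.position - named["CB"].position)
                + named["CB"].position
            )
            for a in side
        }
        variants.append(
            replace(
                pose,
                atoms=tuple(moved.get(id(a), a) for a in pose.atoms),
            )
        )
    return variants


def optimize_pose(
    pose: DesignPose,
    fibril: ZipperModel | None = None,
    weights=None,
    tip: TipInterface | None = None,
    seed: int = 0,
    max_translation: float = 1.0,
    max_rotation: float = 10.0,
    max_sweeps: int = 6,
    score_options: Mapping | None = None,
) -> DesignPose:
    """Greedy coordinate descent on the composite energy.

    Moves: translations of ±0.4/0.2/0.1 Å along the tip frame axes and
    rotations of ±4/2/1° about the pose centroid, bounded by
    ``max_translation`` / ``max_rotation`` from the threaded position, plus
    discrete χ1 rotamer swaps. Fully deterministic; ``seed`` is accepted for
    interface uniformity and logged. Returns a pose whose composite energy
    never exceeds the input pose's; if the starting score is non-finite the
    input pose is returned with ``optimization_failed`` set.
    """
    from . import scoring  # local import: scoring depends on this module

    if tip is None:
        if fibril is None:
            raise ValidationError("optimize_pose needs a fibril or a tip")
        top, bottom = extract_tips(fibril)
        tip = top if pose.face == "top" else bottom
    weights = weights or scoring.ScoreWeights()
    opts = dict(score_options or {})
    logger.debug("optimize_pose seed=%d (search is deterministic)", seed)

    # Inner-loop objective: steepened clash and the H-bond term, with a
    # smooth pairwise contact attraction standing in for the buried-area
    # term (dot-sampled SASA has a discretization ripple that traps a greedy
    # search; the Sc statistic is a selection criterion, not a packing
    # force). The attraction only sees the capped sheet, whose stack is
    # symmetric about the threading register; clash sees everything. The
    # full composite is re-evaluated at the end and the input pose is
    # returned unchanged if the search did not improve it.
    context = list(tip.context_atoms) + list(tip.mating_sheet_atoms)

    ctx_backbone = [
        a for a in tip.context_atoms if a.name in ("N", "CA", "C", "O")
    ]

    def energy(p: DesignPose) -> float:
        clash = scoring.clash_score(p.atoms, context)
        hb = scoring.smooth_hbond(p, tip)
        backbone = [a for a in p.atoms if a.name in ("N", "CA", "C", "O")]
        contact = scoring.smooth_contact(
            backbone, ctx_backbone, width=1.0, scale=0.3
        )
        return 20.0 * weights.clash * clash - 2.0 * weights.hbond * hb - contact

    def full_composite(p: DesignPose) -> float:
        return scoring.score_pose(p, tip, weights, **opts).composite_energy

    e0 = energy(pose)
    if not np.isfinite(e0) or not np.isfinite(full_composite(pose)):
        return replace(pose, optimization_failed=True)

    ez = np.asarray(tip.axis, float)
    ex = np.array([1.0, 0.0, 0.0])
    if abs(ex @ ez) > 0.9:
        ex = np.array([0.0, 1.0, 0.0])
    ex = ex - (ex @ ez) * ez
    ex /= np.linalg.norm(ex)
    ey = np.cross(ez, ex)

    current, e_cur = pose, e0
    start_translation = pose.rigid_translation.copy()
    start_rotation = pose.rigid_rotation.copy()

    def descend(moves: list[tuple[np.ndarray, np.ndarray]]):
        """Steepest-descent sweeps over a fixed move set."""
        nonlocal current, e_cur
        for _ in range(max_sweeps):
            best_trial, best_e = None, e_cur
            for rot, trans in moves:
                trial = current.transformed(rot, trans)
                if (
                    np.linalg.norm(
                        trial.rigid_translation - start_translation
                    )
                    > max_translation
                ):
                    continue
                # net rotation angle from the start orientation
                net = trial.rigid_rotation @ start_rotation.T
                cos_a = np.clip((np.trace(net) - 1.0) / 2.0, -1.0, 1.0)
                if np.degrees(np.arccos(cos_a)) > max_rotation:
                    continue
                e_try = energy(trial)
                if e_try < best_e - 1e-9:
                    best_trial, best_e = trial, e_try
            if best_trial is None:
                break
            current, e_cur = best_trial, best_e

    # Translations settle the register first; rotations then polish the
    # orientation. Interleaving the two lets a greedy search trade a small
    # tilt for a lateral slip and wander off register, so the phases are
    # kept separate and alternated.
    for _phase in range(2):
        for step in (0.4, 0.2, 0.1):
            descend([
                (np.eye(3), s * d)
                for d in (ex, ey, ez)
                for s in (step, -step)
            ])
        for angle in (4.0, 2.0, 1.0):
            descend([
                (rotation_matrix(axis, s), np.zeros(3))
                for axis in (ex, ey, ez)
                for s in (angle, -angle)
            ])

    # discrete rotamer pass
    for res_idx in sorted(current.residues()):
        for trial in _rotamer_variants(current, res_idx):
            e_try = energy(trial)
            if e_try < e_cur - 1e-9:
                current, e_cur = trial, e_try

    # guarantee: never hand back a pose worse than the input under the full
    # composite energy
    if full_composite(current) > full_composite(pose):
        return pose
    return current


# ---------------------------------------------------------------------------
# Fix-and-redesign
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScoredCandidate:
    candidate: CandidateInhibitor
    energy: float
    face: str


def fix_and_redesign(
    tip: TipInterface,
    fibril: ZipperModel,
    alphabet: Mapping[int, Sequence[str]],
    weights=None,
    rounds: int = 3,
    seed: int = 0,
    base_candidate: CandidateInhibitor | None = None,
    score_options: Mapping | None = None,
) -> list[ScoredCandidate]:
    """Iterative greedy sequence design against one tip.

    Each round scans all single-position substitutions over the per-position
    alphabet, fixes the best-scoring residue at its position, and continues
    on the remaining positions. The design objective is the composite
    binding energy minus the mating-sheet disruption reward (see scoring);
    it is non-increasing across rounds. Returns every evaluated sequence
    ranked by energy. Deterministic given the (unused, logged) seed.
    """
    from . import scoring

    if rounds < 1:
        raise ValidationError("rounds must be >= 1")
    if not alphabet:
        raise ValidationError("alphabet must not be empty")
    for pos, letters in alphabet.items():
        if not letters:
            raise ValidationError(f"empty alphabet at position {pos}")
    weights = weights or scoring.ScoreWeights()
    opts = dict(score_options or {})
    logger.debug("fix_and_redesign seed=%d (search is deterministic)", seed)

    if base_candidate is None:
        lo, hi = tip.template_span
        base_candidate = CandidateInhibitor(
            label="design",
            core_sequence=tip.template_sequence,
            start_position=lo,
        )
    # clamp the start sequence into the alphabet
    current = base_candidate
    for pos in sorted(alphabet):
        letters = tuple(alphabet[pos])
        if current.residue_at(pos) not in letters:
            current = current.with_substitution(pos, letters[0])

    evaluated: dict[str, ScoredCandidate] = {}

    def design_energy(cand: CandidateInhibitor) -> float:
        key = cand.effective_sequence
        if key not in evaluated:
            pose = thread_sequence(tip, cand)
            score = scoring.score_pose(pose, tip, weights, **opts)
            e = scoring.design_objective(score, weights)
            evaluated[key] = ScoredCandidate(
                candidate=replace(cand, label=key), energy=e, face=tip.face
            )
        return evaluated[key].energy

    e_cur = design_energy(current)
    fixed: set[int] = set()
    history = [e_cur]
    for _ in range(rounds):
        open_positions = [p for p in sorted(alphabet) if p not in fixed]
        if not open_positions:
            break
        best: tuple[float, int, str] | None = None
        for pos in open_positions:
            for letter in alphabet[pos]:
                cand = current.with_substitution(pos, letter)
                e = design_energy(cand)
                if best is None or e < best[0]:
                    best = (e, pos, letter)
        assert best is not None
        e_best, pos, letter = best
        if e_best < e_cur:
            current = current.with_substitution(pos, letter)
            e_cur = e_best
        else:
            # nothing improves: fix the best open position at its current
            # residue (energy unchanged)
            pos = open_positions[0]
        fixed.add(pos)
        history.append(e_cur)

    assert all(b <= a + 1e-9 for a, b in zip(history, history[1:])), (
        "design energy increased across rounds"
    )
    ranked = sorted(
        evaluated.values(), key=lambda sc: (sc.energy, sc.candidate.label)
    )
    return ranked
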