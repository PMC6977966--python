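"""Interface scoring of capping poses.

Score terms, all in the package's own arbitrary units (no force-field
energies are reproduced; acceptance of a design is ordinal):

* ``clash`` — soft steric repulsion Σ max(0, r_vdw_sum − d)² between pose
  heavy atoms and the existing fibril context. What the pose must avoid to
  bind.
* ``mating_disruption`` — the same repulsion against a *virtual* next strand
  of the opposing sheet, placed at the vacant lattice site adjacent to the
  pose. This is the designed steric clash that blocks further growth of the
  mating sheet; it is reported separately and rewarded (not penalized) by
  the design objective.
* ``hbond_count`` — backbone N–H···O=C pairs across the interface (N···O ≤
  3.5 Å, donor present; N-methylated positions have no donor).
* ``electro_penalty`` — net-formal-charge product heuristic for stacking
  repulsion of charged tags.
* ``buried_area`` — Shrake–Rupley buried solvent-accessible area, Å².
* ``sc`` — Lawrence–Colman-style shape complementarity in [−1, 1].

The composite binding energy is the weighted sum
``+w_clash·clash − w_hb·hbonds − w_bsa·BSA − w_sc·Sc + w_el·electro``
(lower = better binding).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .atoms import AtomRecord, FORMAL_CHARGES
from .candidates import CandidateInhibitor
from .design import DesignPose, optimize_pose, thread_sequence
from .errors import ScoringError, ValidationError
from .sasa import DEFAULT_N_POINTS, PROBE_RADIUS, sasa_per_atom
from .zipper import TipInterface, ZipperModel, extract_tips

HBOND_NO_CUTOFF = 3.5  # Å, donor N to acceptor O
HBOND_HO_CUTOFF = 2.6  # Å, amide H to acceptor O (directionality, if H known)
SC_WEIGHT = 0.5  # Å^-2, Gaussian distance weight in the Sc statistic
SC_DOT_DENSITY = 15.0  # dots per Å² of vdW surface
SC_INTERFACE_CUTOFF = 1.5  # Å, dot counts as buried if partner surface closer
SC_MIN_BURIED_AREA = 10.0  # Å², below this Sc is undefined


@dataclass(frozen=True)
class ScoreWeights:
    """Weights of the composite energy (all non-negative).

    ``mating_disrupt`` weights the disruption reward in the *design*
    objective only; the binding composite never includes it.
    """

    clash: float = 4.0
    hbond: float = 2.0
    bsa: float = 0.05
    sc: float = 10.0
    electro: float = 1.0
    mating_disrupt: float = 0.0
    sc_scale: float = 1.0

    def __post_init__(self):
        for name in ("clash", "hbond", "bsa", "sc", "electro",
                     "mating_disrupt"):
            if getattr(self, name) < 0:
                raise ValidationError(f"weight {name} must be >= 0")


@dataclass(frozen=True)
class InterfaceScore:
    """Per-tip score vector of one pose."""

    clash: float
    hbond_count: int
    electro_penalty: float
    buried_area: float
    sc: float | None  # None = undefined (no buried interface)
    composite_energy: float
    face: str
    mating_disruption: float = 0.0


@dataclass(frozen=True)
class TipVerdict:
    """Binding verdict of one candidate on both fibril ends."""

    top_score: InterfaceScore
    bottom_score: InterfaceScore
    binds_top: bool
    binds_bottom: bool
    threshold: float


def _heavy(atoms: Iterable[AtomRecord]) -> list[AtomRecord]:
    return [a for a in atoms if a.element != "H"]


def _xyz_r(atoms: Sequence[AtomRecord]):
    xyz = np.array([a.position for a in atoms], float).reshape(-1, 3)
    r = np.array([a.vdw for a in atoms], float)
    return xyz, r


# ---------------------------------------------------------------------------
# Clash
# ---------------------------------------------------------------------------

def clash_score(
    pose_atoms: Sequence[AtomRecord], context_atoms: Sequence[AtomRecord]
) -> float:
    """Soft steric repulsion between two heavy-atom sets.

    Σ over cross pairs of max(0, r_vdw(a)+r_vdw(b) − d)²; zero when no pair
    is inside vdW contact; symmetric in its arguments.
    """
    pa, pb = _heavy(pose_atoms), _heavy(context_atoms)
    if not pa or not pb:
        raise ValidationError("clash_score needs two non-empty atom sets")
    xa, ra = _xyz_r(pa)
    xb, rb = _xyz_r(pb)
    rmax = float(ra.max() + rb.max())
    tree = cKDTree(xb)
    total = 0.0
    for i, (x, r) in enumerate(zip(xa, ra)):
        for j in tree.query_ball_point(x, r + rb.max()):
            d = float(np.linalg.norm(x - xb[j]))
            overlap = r + rb[j] - d
            if overlap > 0:
                total += overlap * overlap
    return total


def smooth_contact(
    pose_atoms: Sequence[AtomRecord],
    context_atoms: Sequence[AtomRecord],
    width: float = 0.8,
    offset: float = 0.3,
    scale: float = 0.5,
) -> float:
    """Smooth cross-interface contact attraction.

    Σ over heavy-atom cross pairs of scale·exp(−(d − d₀)²/(2·width²)) with
    d₀ = r_vdw sum + offset: a ripple-free stand-in for buried area used by
    the rigid-body search (dot-sampled SASA is piecewise constant in the
    displacement).
    """
    pa, pb = _heavy(pose_atoms), _heavy(context_atoms)
    if not pa or not pb:
        return 0.0
    xa, ra = _xyz_r(pa)
    xb, rb = _xyz_r(pb)
    tree = cKDTree(xb)
    cutoff = float(ra.max() + rb.max()) + offset + 3.0 * width
    total = 0.0
    for x, r in zip(xa, ra):
        for j in tree.query_ball_point(x, cutoff):
            d = float(np.linalg.norm(x - xb[j]))
            d0 = r + rb[j] + offset
            total += np.exp(-((d - d0) ** 2) / (2.0 * width * width))
    return scale * total


# ---------------------------------------------------------------------------
# Hydrogen bonds
# ---------------------------------------------------------------------------

def _residue_groups(atoms: Sequence[AtomRecord]):
    groups: dict[tuple[str, int], dict[str, AtomRecord]] = {}
    for a in atoms:
        groups.setdefault((a.chain_id, a.residue_index), {})[a.name] = a
    return groups


def _donors_acceptors(atoms: Sequence[AtomRecord], label: str):
    """Backbone donors (N position, H position or None) and acceptor O
    positions."""
    groups = _residue_groups(atoms)
    has_explicit_h = any(a.element == "H" for a in atoms)
    donors, acceptors = [], []
    for (chain, idx), named in groups.items():
        if "N" not in named or "O" not in named:
            raise ScoringError(
                f"{label}: residue {chain}/{idx} lacks backbone N/O atoms"
            )
        acceptors.append(named["O"].position)
        if named["N"].residue_name == "PRO" or "CN" in named:
            continue  # no amide donor
        if has_explicit_h and "H" not in named:
            continue  # explicitly deprotonated position in an H-bearing model
        donors.append((named["N"].position, named.get("H")))
    return donors, acceptors


def hbond_count(pose: DesignPose, tip: TipInterface) -> int:
    """Backbone N–H···O=C pairs across the pose/fibril interface.

    Counts donor–acceptor pairs with N···O ≤ 3.5 Å in both directions
    (pose donors to fibril acceptors and vice versa). N-methylated pose
    positions contribute no donor.
    """
    pd_, pa = _donors_acceptors(pose.atoms, "pose")
    cd, ca = _donors_acceptors(tip.context_atoms, "context")

    count = 0
    for donors, acceptors in ((pd_, ca), (cd, pa)):
        if not donors or not acceptors:
            continue
        acc = np.asarray(acceptors)
        tree = cKDTree(acc)
        for npos, h in donors:
            # one amide hydrogen donates at most one bond, and when the
            # hydrogen is modeled it must point at the acceptor
            for j in tree.query_ball_point(npos, HBOND_NO_CUTOFF):
                if (
                    h is None
                    or np.linalg.norm(h.position - acc[j]) <= HBOND_HO_CUTOFF
                ):
                    count += 1
                    break
    return count


def smooth_hbond(pose: DesignPose, tip: TipInterface,
                 ideal_ho: float = 2.1, width: float = 0.4) -> float:
    """Smooth, directional interface H-bond reward for the rigid search.

    Each donor contributes the best Gaussian score exp(−(d_H···O −
    ideal)²/(2·width²)) over acceptors (N···O proxy minus 1 Å when the
    hydrogen is not modeled); ~1 per well-formed β-sheet bond. Unlike the
    integer :func:`hbond_count`, this is smooth in the pose coordinates, so
    a greedy search can follow it back to register.
    """
    pd_, pa = _donors_acceptors(pose.atoms, "pose")
    cd, ca = _donors_acceptors(tip.context_atoms, "context")
    total = 0.0
    for donors, acceptors in ((pd_, ca), (cd, pa)):
        if not donors or not acceptors:
            continue
        acc = np.asarray(acceptors)
        tree = cKDTree(acc)
        for npos, h in donors:
            best = 0.0
            for j in tree.query_ball_point(npos, HBOND_NO_CUTOFF + 1.5):
                if h is not None:
                    d = float(np.linalg.norm(h.position - acc[j]))
                else:
                    d = float(np.linalg.norm(npos - acc[j])) - 1.0
                best = max(
                    best,
                    float(
                        np.exp(
                            -((d - ideal_ho) ** 2) / (2.0 * width * width)
                        )
                    ),
                )
            total += best
    return total


# ---------------------------------------------------------------------------
# Electrostatic stacking heuristic
# ---------------------------------------------------------------------------

def sequence_charge(sequence: str) -> int:
    return sum(FORMAL_CHARGES.get(letter, 0) for letter in sequence)


def electro_stack_penalty(
    candidate: CandidateInhibitor,
    stack_partner: CandidateInhibitor | None = None,
) -> float:
    """Charge–charge stacking repulsion heuristic.

    Product of the net formal charges (core + tag) of the candidate and its
    stacking partner, clipped below at zero. Called with itself (default) it
    is the self-stacking repulsion used by the self-aggregation score.
    """
    qa = candidate.net_charge()
    qb = (stack_partner or candidate).net_charge()
    return float(max(0, qa * qb))


# ---------------------------------------------------------------------------
# Buried surface area
# ---------------------------------------------------------------------------

def _fibril_side(tip: TipInterface) -> list[AtomRecord]:
    return list(tip.context_atoms) + list(tip.mating_sheet_atoms)


def buried_surface_area(
    pose: DesignPose | Sequence[AtomRecord],
    tip: TipInterface,
    fibril: ZipperModel | None = None,
    n_points: int = DEFAULT_N_POINTS,
    probe: float = PROBE_RADIUS,
) -> float:
    """Buried SASA of the pose/fibril interface, Å².

    BSA = SASA(peptide alone) + SASA(fibril side alone) − SASA(complex),
    probe 1.4 Å, Shrake–Rupley sampling over heavy atoms. Fibril atoms far
    from the pose contribute identically to both terms and are skipped
    exactly, not approximately.
    """
    pose_atoms = _heavy(pose.atoms if isinstance(pose, DesignPose) else pose)
    ctx_atoms = _heavy(_fibril_side(tip))
    if not pose_atoms or not ctx_atoms:
        return 0.0
    px, pr = _xyz_r(pose_atoms)
    cx, cr = _xyz_r(ctx_atoms)

    # context atoms whose sphere could touch a pose sphere (max radius sum
    # plus both probe inflations)
    margin = float(pr.max() + cr.max()) + 2.0 * probe
    tree = cKDTree(px)
    near = np.array(
        [
            i
            for i, x in enumerate(cx)
            if tree.query_ball_point(x, margin, return_length=True) > 0
        ],
        dtype=int,
    )
    if near.size == 0:
        return 0.0

    both_x = np.vstack([px, cx])
    both_r = np.concatenate([pr, cr])
    n_pose = len(px)

    pose_alone = sasa_per_atom(px, pr, probe, n_points)
    pose_complex = sasa_per_atom(
        both_x, both_r, probe, n_points, subset=np.arange(n_pose)
    )
    ctx_alone = sasa_per_atom(cx, cr, probe, n_points, subset=near)
    ctx_complex = sasa_per_atom(
        both_x, both_r, probe, n_points, subset=near + n_pose
    )
    return float(
        (pose_alone.sum() - pose_complex.sum())
        + (ctx_alone.sum() - ctx_complex.sum())
    )


# ---------------------------------------------------------------------------
# Shape complementarity
# ---------------------------------------------------------------------------

def surface_dots(
    atoms: Sequence[AtomRecord], density: float = SC_DOT_DENSITY
):
    """Dots and outward normals on the exposed vdW surface of an atom set."""
    from .geometry import sphere_points

    heavy = _heavy(atoms)
    xyz, r = _xyz_r(heavy)
    tree = cKDTree(xyz)
    dots, normals = [], []
    for i, (x, ri) in enumerate(zip(xyz, r)):
        n_i = max(8, int(round(density * 4.0 * np.pi * ri * ri)))
        unit = sphere_points(n_i)
        pts = x + ri * unit
        neigh = [j for j in tree.query_ball_point(x, ri + r.max()) if j != i]
        if neigh:
            nc = xyz[neigh]
            nr = r[np.asarray(neigh)]
            d2 = np.sum((pts[:, None, :] - nc[None, :, :]) ** 2, axis=2)
            keep = ~np.any(d2 < (nr**2)[None, :] - 1e-9, axis=1)
        else:
            keep = np.ones(len(pts), bool)
        dots.append(pts[keep])
        normals.append(unit[keep])
    return np.vstack(dots), np.vstack(normals)


def sc_from_dots(
    dots_a: np.ndarray,
    normals_a: np.ndarray,
    dots_b: np.ndarray,
    normals_b: np.ndarray,
    w: float = SC_WEIGHT,
    interface_cutoff: float | None = None,
) -> float | None:
    """Shape-complementarity statistic from two dot surfaces.

    For each dot on one surface, find the nearest dot on the partner
    surface and score exp(−w·d²)·(n̂_a·(−n̂_b)); take the median per
    surface and average the two medians. With ``interface_cutoff`` set,
    only dots whose partner surface lies within that distance (the buried
    band) contribute; returns None when either buried band is empty.
    """
    medians = []
    for da, na, db, nb in (
        (dots_a, normals_a, dots_b, normals_b),
        (dots_b, normals_b, dots_a, normals_a),
    ):
        if len(da) == 0 or len(db) == 0:
            return None
        tree = cKDTree(db)
        dist, j = tree.query(da)
        if interface_cutoff is not None:
            mask = dist <= interface_cutoff
            if not mask.any():
                return None
            dist, j, na_sel = dist[mask], j[mask], na[mask]
        else:
            na_sel = na
        scores = np.exp(-w * dist**2) * np.sum(na_sel * (-nb[j]), axis=1)
        medians.append(float(np.median(scores)))
    return float(np.mean(medians))


def shape_complementarity(
    pose: DesignPose | Sequence[AtomRecord],
    tip: TipInterface,
    w: float = SC_WEIGHT,
    density: float = SC_DOT_DENSITY,
    interface_cutoff: float = SC_INTERFACE_CUTOFF,
) -> float | None:
    """Sc of the pose against the fibril side of the tip; None if the two
    surfaces share no buried band."""
    pose_atoms = _heavy(pose.atoms if isinstance(pose, DesignPose) else pose)
    ctx_atoms = _heavy(_fibril_side(tip))
    if not pose_atoms or not ctx_atoms:
        return None
    # only fibril atoms near the pose can host buried dots
    px, pr = _xyz_r(pose_atoms)
    tree = cKDTree(px)
    margin = 2.0 * max(float(pr.max()), 2.0) + interface_cutoff
    ctx_near = [
        a
        for a in ctx_atoms
        if tree.query_ball_point(a.position, margin, return_length=True) > 0
    ]
    if not ctx_near:
        return None
    da, na = surface_dots(pose_atoms, density)
    db, nb = surface_dots(ctx_near, density)
    return sc_from_dots(da, na, db, nb, w, interface_cutoff)


# ---------------------------------------------------------------------------
# Composite energy and verdicts
# ---------------------------------------------------------------------------

def composite_energy(
    clash: float,
    hbonds: float,
    buried_area: float,
    sc: float | None,
    electro: float,
    weights: ScoreWeights,
) -> float:
    """Weighted binding energy; lower = better. An undefined Sc contributes
    nothing."""
    return (
        weights.clash * clash
        - weights.hbond * hbonds
        - weights.bsa * buried_area
        - weights.sc * (sc if sc is not None else 0.0) * weights.sc_scale
        + weights.electro * electro
    )


def virtual_next_mating_strand(tip: TipInterface) -> list[AtomRecord]:
    """The opposing sheet's next incoming strand: its outermost existing
    strand translated one rise outward. Empty if the tip has no mating
    atoms."""
    if not tip.mating_sheet_atoms:
        return []
    outward = tip.outward
    by_strand: dict[str, list[AtomRecord]] = {}
    for a in tip.mating_sheet_atoms:
        by_strand.setdefault(a.chain_id, []).append(a)
    proj = {
        cid: float(np.mean([a.position @ outward for a in atoms]))
        for cid, atoms in by_strand.items()
    }
    outer = max(proj, key=proj.get)
    shift = tip.rise * outward
    return [a.moved(a.position + shift) for a in by_strand[outer]]


def score_pose(
    pose: DesignPose,
    tip: TipInterface,
    weights: ScoreWeights | None = None,
    n_sasa_points: int = DEFAULT_N_POINTS,
    sc_density: float = SC_DOT_DENSITY,
    partner_charge: int | None = None,
    compute_sc: bool = True,
) -> InterfaceScore:
    """All score terms of a pose at a tip.

    ``partner_charge`` is the net formal charge of the stacking partner; by
    default it is the fibril strand's own sequence charge (zero for the
    NACore template), so charged tags penalize self-stacking but not fibril
    binding.
    """
    weights = weights or ScoreWeights()
    existing = _fibril_side(tip)
    clash = clash_score(pose.atoms, existing)
    hbonds = hbond_count(pose, tip)
    if partner_charge is None:
        partner_charge = sequence_charge(tip.template_sequence)
    electro = float(max(0, pose.candidate.net_charge() * partner_charge))
    bsa = buried_surface_area(pose, tip, n_points=n_sasa_points)
    sc = None
    if compute_sc and bsa > SC_MIN_BURIED_AREA:
        sc = shape_complementarity(pose, tip, density=sc_density)
    virtual = virtual_next_mating_strand(tip)
    disruption = clash_score(pose.atoms, virtual) if virtual else 0.0
    return InterfaceScore(
        clash=clash,
        hbond_count=hbonds,
        electro_penalty=electro,
        buried_area=bsa,
        sc=sc,
        composite_energy=composite_energy(
            clash, hbonds, bsa, sc, electro, weights
        ),
        face=tip.face,
        mating_disruption=disruption,
    )


def design_objective(score: InterfaceScore, weights: ScoreWeights) -> float:
    """Objective minimized by sequence design: binding energy minus the
    mating-sheet disruption reward."""
    return score.composite_energy - weights.mating_disrupt * score.mating_disruption


def native_candidate(tip: TipInterface, span=None) -> CandidateInhibitor:
    """The fibril's own sequence over ``span`` (default: full template)."""
    lo, hi = tip.template_span
    if span is not None:
        lo, hi = span
    seq = tip.template_sequence[
        lo - tip.template_span[0] : hi - tip.template_span[0] + 1
    ]
    return CandidateInhibitor(
        label="native", core_sequence=seq, start_position=lo
    )


def evaluate_both_tips(
    candidate: CandidateInhibitor,
    fibril: ZipperModel,
    weights: ScoreWeights | None = None,
    threshold: float | None = None,
    context_layers: int = 4,
    optimize: bool = False,
    face_energy_offsets: dict[str, float] | None = None,
    n_sasa_points: int = DEFAULT_N_POINTS,
    sc_density: float = SC_DOT_DENSITY,
) -> TipVerdict:
    """Thread (optionally optimize) and score a candidate on both faces.

    ``binds_*`` is composite energy ≤ threshold on that face; the default
    threshold is half the native self-extension energy (averaged over the
    two faces), i.e. a candidate must realize at least half the binding of
    the fibril extending itself. ``face_energy_offsets`` adds a constant to
    a face's composite energy before the verdict (useful for constructed
    asymmetry checks).
    """
    weights = weights or ScoreWeights()
    offsets = face_energy_offsets or {}
    top, bottom = extract_tips(fibril, context_layers)
    tips = {"top": top, "bottom": bottom}

    scores: dict[str, InterfaceScore] = {}
    for face, tip in tips.items():
        pose = thread_sequence(tip, candidate)
        if optimize:
            pose = optimize_pose(
                pose, tip=tip, weights=weights,
                score_options={"n_sasa_points": n_sasa_points,
                               "sc_density": sc_density},
            )
        s = score_pose(
            pose, tip, weights,
            n_sasa_points=n_sasa_points, sc_density=sc_density,
        )
        if face in offsets:
            s = replace(
                s, composite_energy=s.composite_energy + offsets[face]
            )
        scores[face] = s

    if threshold is None:
        native_es = []
        for face, tip in tips.items():
            ncand = native_candidate(tip, candidate.span)
            npose = thread_sequence(tip, ncand)
            native_es.append(
                score_pose(
                    npose, tip, weights,
                    n_sasa_points=n_sasa_points, sc_density=sc_density,
                ).composite_energy
            )
        threshold = 0.5 * float(np.mean(native_es))

    return TipVerdict(
        top_score=scores["top"],
        bottom_score=scores["bottom"],
        binds_top=scores["top"].composite_energy <= threshold,
        binds_bottom=scores["bottom"].composite_energy <= threshold,
        threshold=threshold,
    )


def self_aggregation_score(
    candidate: CandidateInhibitor,
    weights: ScoreWeights | None = None,
    n_strands: int = 4,
    context_layers: int = 3,
    n_sasa_points: int = DEFAULT_N_POINTS,
    sc_density: float = SC_DOT_DENSITY,
) -> float:
    """Self-stacking energy of a candidate on a fibril of its own sequence.

    Builds an ideal zipper from the candidate's (modified) core sequence,
    threads the candidate on its top tip and scores it with the candidate
    itself as stacking partner, so the electro penalty is the self-repulsion
    of the tag charge. Higher (worse stacking) = less aggregation-prone.
    """
    from .fixtures import ZipperSpec, build_ideal_zipper

    weights = weights or ScoreWeights()
    zipper = build_ideal_zipper(
        ZipperSpec(
            sequence=candidate.effective_sequence,
            n_strands_per_sheet=n_strands,
            start_residue=candidate.start_position,
        )
    )
    top, _ = extract_tips(zipper, context_layers)
    pose = thread_sequence(top, candidate)
    score = score_pose(
        pose, top, weights,
        n_sasa_points=n_sasa_points, sc_density=sc_density,
        partner_charge=candidate.net_charge(),
    )
    return score.composite_energy


def rank_designs(
    candidates: Sequence[CandidateInhibitor],
    fibril: ZipperModel,
    weights: ScoreWeights | None = None,
    threshold: float | None = None,
    context_layers: int = 4,
    optimize: bool = False,
    n_sasa_points: int = DEFAULT_N_POINTS,
    sc_density: float = SC_DOT_DENSITY,
) -> pd.DataFrame:
    """Rank candidates by best-face composite energy (ascending), ties
    broken by label. One row per candidate with per-face terms, the tip
    verdict and a self-aggregation flag (no stacking charge repulsion)."""
    if not candidates:
        raise ValidationError("need at least one candidate")
    weights = weights or ScoreWeights()
    rows = []
    for cand in candidates:
        verdict = evaluate_both_tips(
            cand, fibril, weights, threshold=threshold,
            context_layers=context_layers, optimize=optimize,
            n_sasa_points=n_sasa_points, sc_density=sc_density,
        )
        best_face = (
            "top"
            if verdict.top_score.composite_energy
            <= verdict.bottom_score.composite_energy
            else "bottom"
        )
        best = getattr(verdict, f"{best_face}_score")
        rows.append(
            {
                "label": cand.label,
                "sequence": cand.effective_sequence,
                "best_face": best_face,
                "energy": best.composite_energy,
                "energy_top": verdict.top_score.composite_energy,
                "energy_bottom": verdict.bottom_score.composite_energy,
                "binds_top": verdict.binds_top,
                "binds_bottom": verdict.binds_bottom,
                "sc": best.sc,
                "buried_area": best.buried_area,
                "hbonds": best.hbond_count,
                "clash": best.clash,
                "mating_disruption": best.mating_disruption,
                "self_aggregation_prone": electro_stack_penalty(cand) == 0,
            }
        )
    report = pd.DataFrame(rows)
    report = report.sort_values(
        ["energy", "label"], kind="stable"
    ).reset_index(drop=True)
    return report


def structure_checksum(model: ZipperModel) -> str:
    """Checksum of a model's coordinates for run logging."""
    h = hashlib.sha256()
    for a in model.atoms:
        h.update(
            f"{a.chain_id}{a.residue_index}{a.name}"
            f"{a.position[0]:.3f}{a.position[1]:.3f}{a.position[2]:.3f}"
            .encode()
        )
    return h.hexdigest()[:16]
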