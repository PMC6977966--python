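"""Interface score terms, verdicts and ranking."""

import dataclasses

import numpy as np
import pytest
from scipy.spatial import cKDTree

from zippercap import (
    CandidateInhibitor,
    Modification,
    ZipperSpec,
    build_ideal_zipper,
    buried_surface_area,
    clash_score,
    composite_energy,
    electro_stack_penalty,
    evaluate_both_tips,
    extract_tips,
    hbond_count,
    rank_designs,
    self_aggregation_score,
    shape_complementarity,
    thread_sequence,
)
from zippercap.atoms import AtomRecord, vdw_radius
from zippercap.errors import ValidationError
from zippercap.geometry import sphere_points
from zippercap.scoring import (
    ScoreWeights,
    native_candidate,
    sc_from_dots,
    score_pose,
)

from conftest import FAST_SCORE, NACORE9


def _carbon(x, y, z, chain="t", idx=1, name="CA"):
    return AtomRecord(
        element="C", name=name, residue_name="ALA", residue_index=idx,
        chain_id=chain, position=np.array([x, y, z], float),
    )


def _random_toy(rng, n, spread=6.0):
    elements = ["C", "N", "O", "S"]
    return [
        AtomRecord(
            element=rng.choice(elements),
            name="X",
            residue_name="ALA",
            residue_index=i,
            chain_id="t",
            position=rng.uniform(-spread, spread, 3),
        )
        for i in range(n)
    ]


class TestClash:
    def test_distant_atoms_do_not_clash(self):
        assert clash_score([_carbon(0, 0, 0)], [_carbon(5, 0, 0)]) == 0.0

    def test_coincident_carbons_closed_form(self):
        r = vdw_radius("C")
        assert clash_score(
            [_carbon(0, 0, 0)], [_carbon(0, 0, 0, chain="u")]
        ) == pytest.approx((2 * r) ** 2)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(0)
        a, b = _random_toy(rng, 8), _random_toy(rng, 8)
        assert clash_score(a, b) == pytest.approx(clash_score(b, a))

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            a, b = _random_toy(rng, 10, 4.0), _random_toy(rng, 10, 4.0)
            expected = 0.0
            for ai in a:
                for bj in b:
                    d = np.linalg.norm(ai.position - bj.position)
                    overlap = ai.vdw + bj.vdw - d
                    if overlap > 0:
                        expected += overlap**2
            assert clash_score(a, b) == pytest.approx(expected, abs=1e-9)


class TestHBonds:
    def test_native_extension_matches_interior_layer(self):
        """A native capping pose is geometrically the next fibril layer, so
        its interface H-bond count equals the fibril's own layer-to-layer
        count."""
        m3 = build_ideal_zipper(
            ZipperSpec(sequence=NACORE9, n_strands_per_sheet=3)
        )
        m4 = build_ideal_zipper(
            ZipperSpec(sequence=NACORE9, n_strands_per_sheet=4)
        )
        top3, _ = extract_tips(m3, context_layers=2)
        pose = thread_sequence(top3, native_candidate(top3))
        threaded_count = hbond_count(pose, top3)

        # the real strand occupying that lattice site in the larger fibril
        top4, _ = extract_tips(m4, context_layers=2)
        real = dataclasses.replace(
            pose, atoms=tuple(top4.template_atoms)
        )
        assert threaded_count == hbond_count(real, top3)
        assert threaded_count == 8  # one bond per donor on a 9-mer

    def test_n_methylation_removes_exactly_one_interface_bond(self,
                                                              top_tip):
        plain = thread_sequence(top_tip, native_candidate(top_tip))
        meth = thread_sequence(
            top_tip,
            CandidateInhibitor(
                label="m",
                core_sequence=NACORE9,
                modifications=(Modification(73, "n_methylation"),),
            ),
        )
        assert hbond_count(meth, top_tip) == hbond_count(plain, top_tip) - 1

    def test_lifted_pose_has_no_bonds(self, top_tip, native_pose):
        lifted = native_pose.transformed(np.eye(3), np.array([0, 0, 5.0]))
        assert hbond_count(lifted, top_tip) == 0

    def test_missing_backbone_atoms_name_the_residue(self, top_tip,
                                                     native_pose):
        from zippercap.errors import ScoringError

        gutted = dataclasses.replace(
            native_pose,
            atoms=tuple(
                a for a in native_pose.atoms
                if not (a.residue_index == 72 and a.name == "O")
            ),
        )
        with pytest.raises(ScoringError, match="72"):
            hbond_count(gutted, top_tip)


class TestElectro:
    def test_neutral_pair_is_zero(self):
        a = CandidateInhibitor(label="a", core_sequence=NACORE9)
        assert electro_stack_penalty(a, a) == 0.0

    def test_polyk_self_product(self):
        c = CandidateInhibitor(
            label="c", core_sequence=NACORE9, tag="poly_lysine"
        )
        assert electro_stack_penalty(c, c) == 16.0

    def test_tat_self_product(self):
        c = CandidateInhibitor(label="c", core_sequence=NACORE9, tag="tat")
        # default TAT sequence YGRKKRRQRRR carries +8
        assert electro_stack_penalty(c, c) == 64.0

    def test_opposite_charges_clip_to_zero(self):
        pos = CandidateInhibitor(
            label="p", core_sequence=NACORE9, tag="poly_lysine"
        )
        neg = CandidateInhibitor(label="n", core_sequence="AVVEGVEAV")
        assert electro_stack_penalty(pos, neg) == 0.0


class TestBuriedArea:
    def test_distant_peptide_buries_nothing(self, top_tip, native_pose):
        far = native_pose.transformed(np.eye(3), np.array([0, 50.0, 0]))
        assert buried_surface_area(far, top_tip) < 1.0

    def test_native_pose_buries_large_interface(self, top_tip,
                                                native_pose):
        assert buried_surface_area(native_pose, top_tip) > 300.0

    def test_dense_sampling_regression(self, top_tip, native_pose):
        # frozen from a dense (1024-point) reference run of this fixture
        assert buried_surface_area(
            native_pose, top_tip, n_points=1024
        ) == pytest.approx(571.2, abs=1.0)

    def test_sampling_convergence(self, top_tip, native_pose):
        coarse = buried_surface_area(native_pose, top_tip, n_points=512)
        fine = buried_surface_area(native_pose, top_tip, n_points=1024)
        assert abs(fine - coarse) / fine < 0.02

    def test_matches_independent_sasa_oracle(self):
        """BSA of a small toy vs a plainly-coded SASA difference using an
        independent (random-direction) sphere sampling."""
        rng = np.random.default_rng(3)
        side_a = _random_toy(rng, 12, 3.0)
        side_b = [
            dataclasses.replace(a, position=a.position + np.array([4.0, 0, 0]))
            for a in _random_toy(rng, 12, 3.0)
        ]

        def oracle_sasa(atoms, probe=1.4, n=2000):
            pts = rng.normal(size=(n, 3))
            pts /= np.linalg.norm(pts, axis=1)[:, None]
            total = 0.0
            for i, ai in enumerate(atoms):
                ri = ai.vdw + probe
                surface = ai.position + ri * pts
                exposed = np.ones(n, bool)
                for j, aj in enumerate(atoms):
                    if i == j:
                        continue
                    rj = aj.vdw + probe
                    d = np.linalg.norm(surface - aj.position, axis=1)
                    exposed &= d >= rj
                total += 4 * np.pi * ri * ri * exposed.mean()
            return total

        expected = (
            oracle_sasa(side_a)
            + oracle_sasa(side_b)
            - oracle_sasa(side_a + side_b)
        )
        from zippercap.sasa import sasa_per_atom

        def pkg_sasa(atoms):
            xyz = np.array([a.position for a in atoms])
            r = np.array([a.vdw for a in atoms])
            return float(sasa_per_atom(xyz, r, n_points=512).sum())

        got = pkg_sasa(side_a) + pkg_sasa(side_b) - pkg_sasa(side_a + side_b)
        assert got == pytest.approx(expected, rel=0.05, abs=2.0)


class TestShapeComplementarity:
    def _wall(self, z, normal_z, n=15):
        xs, ys = np.meshgrid(np.linspace(0, 7, n), np.linspace(0, 7, n))
        dots = np.column_stack(
            [xs.ravel(), ys.ravel(), np.full(n * n, float(z))]
        )
        normals = np.tile([0.0, 0.0, float(normal_z)], (n * n, 1))
        return dots, normals

    def test_perfectly_mating_walls_score_one(self):
        da, na = self._wall(0.0, +1.0)
        db, nb = self._wall(0.0, -1.0)
        assert sc_from_dots(da, na, db, nb) == pytest.approx(1.0, abs=0.02)

    def test_orthogonal_normals_score_near_zero(self):
        da, na = self._wall(0.0, +1.0)
        db, _ = self._wall(0.0, -1.0)
        nb = np.tile([1.0, 0.0, 0.0], (len(db), 1))
        assert sc_from_dots(da, na, db, nb) <= 0.1

    def test_molecular_sc_is_bounded(self, top_tip, native_pose):
        for shift in (0.0, 0.5, 1.0):
            pose = native_pose.transformed(
                np.eye(3), np.array([0, 0, shift])
            )
            sc = shape_complementarity(pose, top_tip, density=5.0)
            if sc is not None:
                assert -1.0 <= sc <= 1.0

    def test_no_interface_is_undefined(self, top_tip, native_pose):
        far = native_pose.transformed(np.eye(3), np.array([0, 40.0, 0]))
        assert shape_complementarity(far, top_tip) is None

    def test_agrees_with_independent_dot_oracle(self):
        """Sc of a two-sphere toy interface computed with the package's
        golden-spiral dots vs an oracle using rejection-sampled random dots
        and its own nearest-neighbor/median code."""
        a = [_carbon(0, 0, 0)]
        b = [_carbon(0, 0, 3.6, chain="u")]
        pkg = sc_from_dots(
            *_pkg_dots(a), *_pkg_dots(b), interface_cutoff=1.5
        )

        rng = np.random.default_rng(11)
        da, na = _random_sphere_dots(a[0], rng)
        db, nb = _random_sphere_dots(b[0], rng)
        w = 0.5
        meds = []
        for xs, ns, ys, ms in ((da, na, db, nb), (db, nb, da, na)):
            d = np.linalg.norm(xs[:, None] - ys[None, :], axis=2)
            j = d.argmin(axis=1)
            dist = d.min(axis=1)
            keep = dist <= 1.5
            s = np.exp(-w * dist[keep] ** 2) * np.sum(
                ns[keep] * (-ms[j[keep]]), axis=1
            )
            meds.append(np.median(s))
        oracle = float(np.mean(meds))
        assert pkg == pytest.approx(oracle, abs=0.05)


def _pkg_dots(atoms):
    from zippercap.scoring import surface_dots

    return surface_dots(atoms, density=15.0)


def _random_sphere_dots(atom, rng, n=600):
    pts = rng.normal(size=(n, 3))
    pts /= np.linalg.norm(pts, axis=1)[:, None]
    return atom.position + atom.vdw * pts, pts


class TestComposite:
    WEIGHTS = ScoreWeights(clash=4.0, hbond=2.0, bsa=0.05, sc=10.0,
                           electro=1.0)

    def test_all_zero_terms_give_zero(self):
        assert composite_energy(0, 0, 0, 0.0, 0, self.WEIGHTS) == 0.0

    def test_extra_hbond_strictly_lowers_energy(self):
        base = composite_energy(1.0, 5, 400.0, 0.5, 2.0, self.WEIGHTS)
        more = composite_energy(1.0, 6, 400.0, 0.5, 2.0, self.WEIGHTS)
        assert more < base

    def test_hand_computed_weighted_sum(self):
        got = composite_energy(2.0, 8, 500.0, 0.4, 16.0, self.WEIGHTS)
        assert got == pytest.approx(
            4.0 * 2.0 - 2.0 * 8 - 0.05 * 500.0 - 10.0 * 0.4 + 16.0
        )

    def test_undefined_sc_contributes_nothing(self):
        assert composite_energy(0, 0, 0, None, 0, self.WEIGHTS) == 0.0


class TestVerdicts:
    def test_native_binds_both_faces(self, fibril):
        v = evaluate_both_tips(
            native_candidate_for(fibril), fibril, context_layers=2,
            **FAST_SCORE,
        )
        assert v.binds_top and v.binds_bottom

    def test_one_face_penalty_gives_one_face_verdict(self, fibril):
        v = evaluate_both_tips(
            native_candidate_for(fibril), fibril, context_layers=2,
            face_energy_offsets={"top": 1000.0}, **FAST_SCORE,
        )
        assert not v.binds_top
        assert v.binds_bottom

    def test_axis_flip_relabels_faces(self, fibril):
        cand = CandidateInhibitor(
            label="m",
            core_sequence=NACORE9,
            modifications=(Modification(73, "n_methylation"),),
        )
        v = evaluate_both_tips(cand, fibril, context_layers=2,
                               **FAST_SCORE)
        flipped_model = dataclasses.replace(
            fibril, fibril_axis=-fibril.fibril_axis
        )
        w = evaluate_both_tips(cand, flipped_model, context_layers=2,
                               **FAST_SCORE)
        assert v.binds_top == w.binds_bottom
        assert v.binds_bottom == w.binds_top
        assert v.top_score.hbond_count == w.bottom_score.hbond_count

    def test_native_beats_three_angstrom_displacements(self, top_tip,
                                                       native_pose):
        e_native = score_pose(native_pose, top_tip,
                              **FAST_SCORE).composite_energy
        for direction in np.eye(3):
            for sign in (+1, -1):
                displaced = native_pose.transformed(
                    np.eye(3), sign * 3.0 * direction
                )
                e_disp = score_pose(displaced, top_tip,
                                    **FAST_SCORE).composite_energy
                assert e_native < e_disp

    def test_trp72_disrupts_mating_sheet_more_than_native(self, top_tip):
        native = thread_sequence(top_tip, native_candidate(top_tip))
        trp = thread_sequence(
            top_tip,
            CandidateInhibitor(
                label="w",
                core_sequence=NACORE9,
                modifications=(Modification(72, "trp_substitution"),),
            ),
        )
        s_nat = score_pose(native, top_tip, **FAST_SCORE)
        s_trp = score_pose(trp, top_tip, **FAST_SCORE)
        assert s_trp.mating_disruption > s_nat.mating_disruption


def native_candidate_for(fibril):
    top, _ = extract_tips(fibril, context_layers=2)
    return native_candidate(top)


class TestSelfAggregation:
    def test_polyk_tag_worsens_self_stacking(self):
        core = CandidateInhibitor(label="core", core_sequence=NACORE9)
        tagged = CandidateInhibitor(
            label="coreK4", core_sequence=NACORE9, tag="poly_lysine"
        )
        e_core = self_aggregation_score(core, **FAST_SCORE)
        e_tag = self_aggregation_score(tagged, **FAST_SCORE)
        assert e_tag > e_core

    def test_tag_effect_is_exactly_the_electro_term(self):
        """Tags are never built in 3D, so with identical geometry the
        difference must equal the charge-product penalty."""
        weights = ScoreWeights()
        core = CandidateInhibitor(label="core", core_sequence=NACORE9)
        tagged = CandidateInhibitor(
            label="coreK4", core_sequence=NACORE9, tag="poly_lysine"
        )
        diff = self_aggregation_score(
            tagged, weights=weights, **FAST_SCORE
        ) - self_aggregation_score(core, weights=weights, **FAST_SCORE)
        assert diff == pytest.approx(weights.electro * 16.0)


class TestRanking:
    def test_single_candidate_ranks_itself(self, fibril):
        cand = CandidateInhibitor(label="only", core_sequence=NACORE9)
        report = rank_designs([cand], fibril, context_layers=2,
                              **FAST_SCORE)
        assert list(report["label"]) == ["only"]

    def test_equal_energies_tie_break_by_label(self, fibril):
        a = CandidateInhibitor(label="alpha", core_sequence=NACORE9)
        b = CandidateInhibitor(label="beta", core_sequence=NACORE9)
        report = rank_designs([b, a], fibril, context_layers=2,
                              **FAST_SCORE)
        assert list(report["label"]) == ["alpha", "beta"]

    def test_permutation_invariance(self, fibril):
        cands = [
            CandidateInhibitor(label="nat", core_sequence=NACORE9),
            CandidateInhibitor(
                label="trp",
                core_sequence=NACORE9,
                modifications=(Modification(72, "trp_substitution"),),
            ),
            CandidateInhibitor(
                label="meth",
                core_sequence=NACORE9,
                modifications=(Modification(73, "n_methylation"),),
            ),
        ]
        r1 = rank_designs(cands, fibril, context_layers=2, **FAST_SCORE)
        r2 = rank_designs(cands[::-1], fibril, context_layers=2,
                          **FAST_SCORE)
        assert list(r1["label"]) == list(r2["label"])

    def test_empty_candidate_list_rejected(self, fibril):
        with pytest.raises(ValidationError):
            rank_designs([], fibril)
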