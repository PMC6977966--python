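"""Assay models: steady-state SPR fit, ThT folds, puncta, dilutions."""

import math

import numpy as np
import pytest

from zippercap import (
    BindingIsotherm,
    PunctaRecord,
    SynthIsothermSpec,
    ThTCurveSpec,
    dilution_chain,
    dose_response_table,
    fit_steady_state_kd,
    fold_reduction,
    normalize_puncta,
    steady_state_response,
    synth_isotherm,
    synth_tht_curves,
)
from zippercap.errors import ValidationError


class TestSteadyStateFit:
    def test_noiseless_round_trip_is_exact(self):
        iso = synth_isotherm(
            SynthIsothermSpec(
                kd_true=10.0,
                rmax_true=100.0,
                ri_true=5.0,
                concentrations=tuple(np.geomspace(0.5, 500, 11)),
                noise_sd_frac=0.0,
            )
        )
        fit = fit_steady_state_kd(iso)
        assert fit.converged
        assert fit.kd == pytest.approx(10.0, rel=1e-6)
        assert fit.rmax == pytest.approx(100.0, rel=1e-6)
        assert fit.ri == pytest.approx(5.0, rel=1e-5)

    def test_half_saturation_identity_at_fitted_kd(self):
        iso = synth_isotherm(
            SynthIsothermSpec(kd_true=25.0, noise_sd_frac=0.01, seed=5)
        )
        fit = fit_steady_state_kd(iso)
        predicted = steady_state_response(fit.kd, fit.kd, fit.rmax, fit.ri)
        assert predicted == pytest.approx(fit.rmax / 2 + fit.ri)

    def test_monotone_decreasing_responses_flag_non_binding(self):
        iso = BindingIsotherm(
            concentrations=(1.0, 3.0, 10.0, 30.0, 100.0),
            responses=(50.0, 40.0, 30.0, 20.0, 10.0),
        )
        with pytest.warns(UserWarning, match="no binding"):
            fit = fit_steady_state_kd(iso)
        assert not fit.converged

    def test_flat_responses_rejected(self):
        iso = BindingIsotherm(
            concentrations=(1.0, 3.0, 10.0, 30.0, 100.0),
            responses=(5.0,) * 5,
        )
        with pytest.raises(ValidationError):
            fit_steady_state_kd(iso)

    @pytest.mark.parametrize("kd_true", [0.5, 10.0, 300.0])
    def test_recovery_and_coverage_across_affinity_range(self, kd_true):
        """Median fitted KD within 15% of truth and ±2·se coverage ≥ 80%
        at 2% noise over the 0.5–300 µM affinity range."""
        fitted, covered = [], 0
        n_seeds = 100
        for seed in range(1, n_seeds + 1):
            iso = synth_isotherm(
                SynthIsothermSpec(
                    kd_true=kd_true, rmax_true=100.0, ri_true=2.0,
                    noise_sd_frac=0.02, seed=seed,
                )
            )
            fit = fit_steady_state_kd(iso)
            fitted.append(fit.kd)
            if (
                np.isfinite(fit.se_kd)
                and abs(fit.kd - kd_true) <= 2 * fit.se_kd
            ):
                covered += 1
        assert abs(np.median(fitted) - kd_true) / kd_true < 0.15
        assert covered / n_seeds >= 0.80


class TestFoldReduction:
    def test_identical_traces_give_one(self):
        control, _ = synth_tht_curves(
            ThTCurveSpec(control_plateau=500.0, fold_reduction=3.0)
        )
        assert fold_reduction(control, control) == pytest.approx(1.0)

    def test_constructed_fold_recovered_exactly(self):
        control, treated = synth_tht_curves(
            ThTCurveSpec(control_plateau=700.0, fold_reduction=5.0)
        )
        assert fold_reduction(control, treated) == pytest.approx(
            5.0, abs=1e-9
        )

    def test_high_fold_regime_with_noise(self):
        """Emulates a strong-inhibition regime (tens-fold reduction)."""
        folds = [
            fold_reduction(
                *synth_tht_curves(
                    ThTCurveSpec(
                        control_plateau=1000.0, fold_reduction=25.0,
                        noise_sd=10.0, seed=seed,
                    )
                )
            )
            for seed in range(50)
        ]
        assert 24.0 <= np.median(folds) <= 26.0

    def test_scale_invariance(self):
        control, treated = synth_tht_curves(
            ThTCurveSpec(
                control_plateau=800.0, fold_reduction=4.0, noise_sd=5.0,
                seed=2,
            )
        )
        ref = fold_reduction(control, treated)
        for k in (0.1, 3.0, 1e4):
            scaled = [
                type(t)(
                    times=t.times,
                    fluorescence=tuple(k * f for f in t.fluorescence),
                    condition_label=t.condition_label,
                )
                for t in (control, treated)
            ]
            assert fold_reduction(*scaled) == pytest.approx(ref)

    def test_dead_treated_trace_is_infinite_fold(self):
        control, _ = synth_tht_curves(
            ThTCurveSpec(control_plateau=500.0, fold_reduction=2.0)
        )
        flat = type(control)(
            times=control.times,
            fluorescence=(7.0,) * len(control.times),
            condition_label="dead",
        )
        assert math.isinf(fold_reduction(control, flat))


class TestPuncta:
    def test_single_well_arithmetic(self):
        table = normalize_puncta(
            [PunctaRecord(200, 0.5, "A1", "seeded")]
        )
        assert table.loc[0, "mean"] == pytest.approx(400.0)

    def test_all_zero_condition(self):
        table = normalize_puncta(
            [
                PunctaRecord(0, 0.9, f"B{i}", "inhibitor")
                for i in range(3)
            ]
        )
        row = table[table["condition"] == "inhibitor"].iloc[0]
        assert row["mean"] == 0.0 and row["sd"] == 0.0

    def test_triplicate_mean_and_sd(self):
        table = normalize_puncta(
            [
                PunctaRecord(100, 1.0, "C1", "x"),
                PunctaRecord(110, 1.0, "C2", "x"),
                PunctaRecord(120, 1.0, "C3", "x"),
            ]
        )
        row = table.iloc[0]
        assert row["mean"] == pytest.approx(110.0)
        assert row["sd"] == pytest.approx(10.0)

    def test_zero_confluence_rejected_with_warning(self):
        with pytest.warns(UserWarning, match="confluence"):
            table = normalize_puncta(
                [
                    PunctaRecord(10, 0.0, "D1", "x"),
                    PunctaRecord(10, 1.0, "D2", "x"),
                ]
            )
        assert table.iloc[0]["n"] == 1

    def test_homogeneity(self):
        records = [
            PunctaRecord(50, 0.8, "E1", "x"),
            PunctaRecord(70, 0.7, "E2", "x"),
        ]
        doubled = [
            PunctaRecord(2 * r.raw_puncta, r.confluence, r.well_id,
                         r.condition)
            for r in records
        ]
        assert normalize_puncta(doubled).iloc[0]["mean"] == pytest.approx(
            2 * normalize_puncta(records).iloc[0]["mean"]
        )


class TestDilutionChain:
    def test_single_ratio_step(self):
        assert dilution_chain(100.0, [("ratio", 2)]) == pytest.approx(50.0)

    def test_transfection_protocol_reaches_125_nanomolar(self):
        final = dilution_chain(
            50.0, [("ratio", 20), ("ratio", 2), ("volume", 10, 100)]
        )
        assert final == pytest.approx(0.125)

    def test_composition(self):
        a = [("ratio", 5), ("volume", 3, 30)]
        b = [("ratio", 4), ("ratio", 2)]
        chained = dilution_chain(dilution_chain(80.0, a), b)
        assert chained == pytest.approx(dilution_chain(80.0, a + b))

    def test_invalid_steps_rejected(self):
        with pytest.raises(ValidationError):
            dilution_chain(10.0, [("ratio", 0)])
        with pytest.raises(ValidationError):
            dilution_chain(10.0, [("osmosis", 2)])


class TestDoseResponse:
    def test_strictly_decreasing_is_monotone(self):
        out = dose_response_table(
            [(1, 400.0), (2, 300.0), (5, 100.0), (10, 10.0)]
        )
        assert out["monotone_non_increasing"]
        assert out["offending_pair"] is None

    def test_flat_response_is_monotone_and_flagged_flat(self):
        out = dose_response_table([(1, 50.0), (2, 50.0), (5, 50.0)])
        assert out["monotone_non_increasing"]
        assert out["flat"]

    def test_single_inversion_names_the_pair(self):
        out = dose_response_table(
            [(1, 400.0), (2, 300.0), (5, 350.0), (10, 10.0)]
        )
        assert not out["monotone_non_increasing"]
        assert out["offending_pair"] == (2.0, 5.0)

    def test_input_order_does_not_matter(self):
        pairs = [(10, 10.0), (1, 400.0), (5, 100.0), (2, 300.0)]
        out = dose_response_table(pairs)
        assert list(out["table"]["molar_ratio"]) == [1, 2, 5, 10]
        assert out["monotone_non_increasing"]
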