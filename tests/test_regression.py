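"""Log-log threshold regression: frozen predictor, OLS fit, CV, diagnostics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pfacalc as pf
from pfacalc.regression import DegenerateDesignError, _table_xy

positive_params = st.tuples(
    st.integers(min_value=1, max_value=2000),
    st.floats(min_value=0.01, max_value=100.0, allow_nan=False),
    st.floats(min_value=0.1, max_value=1000.0, allow_nan=False),
)


class TestLogFeatures:
    def test_unit_inputs_map_to_zero(self):
        feats = pf.log_features(pf.PulseTrain(1, 1.0, 1.0))
        assert feats == pytest.approx([0.0, 0.0, 0.0], abs=0)

    def test_hand_evaluated_example(self):
        feats = pf.log_features(pf.PulseTrain(400, 0.2, 2.0))
        assert feats == pytest.approx([5.9915, -1.6094, 0.6931], abs=1e-4)

    def test_zero_parameter_is_domain_error(self):
        with pytest.raises(Exception):
            pf.PulseTrain(100, 0.0, 20.0)
        with pytest.raises(ValueError):
            pf.frozen_model().predict([[100, 0.0, 20.0]])


class TestFrozenPredictor:
    def test_reference_prediction(self, frozen):
        assert frozen.predict_train(pf.PulseTrain(400, 0.2, 2.0)) == pytest.approx(
            3.56, abs=5e-3
        )

    def test_all_unit_parameters_give_exp_intercept(self, frozen):
        pred = frozen.predict_train(pf.PulseTrain(1, 1.0, 1.0))
        assert pred == pytest.approx(np.exp(pf.FROZEN_COEFFICIENTS[0]), rel=1e-12)
        assert pred == pytest.approx(11.22, abs=5e-3)

    def test_prediction_near_observed_reference_condition(self, frozen):
        # observed 7.66 ± 0.44 for this condition
        assert frozen.predict_train(pf.PulseTrain(50, 0.2, 200.0)) == pytest.approx(
            7.77, abs=5e-3
        )

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(params=positive_params, factor=st.floats(min_value=1.01, max_value=10))
    def test_monotone_in_each_parameter(self, frozen, params, factor):
        """Threshold falls with more/longer pulses, rises with PRF."""
        p, tp, f = params
        base = frozen.predict_train(pf.PulseTrain(p, tp, f))
        more_pulses = frozen.predict_train(pf.PulseTrain(int(np.ceil(p * factor)) + 1, tp, f))
        longer = frozen.predict_train(pf.PulseTrain(p, tp * factor, f))
        faster = frozen.predict_train(pf.PulseTrain(p, tp, f * factor))
        assert more_pulses < base
        assert longer < base
        assert faster > base

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(params=positive_params)
    def test_prediction_strictly_positive(self, frozen, params):
        p, tp, f = params
        assert frozen.predict_train(pf.PulseTrain(p, tp, f)) > 0


class TestFitting:
    def test_noiseless_synthetic_recovers_frozen_coefficients(
        self, frozen, packaged_table
    ):
        design = [r.train for r in packaged_table]
        synth = pf.generate_synthetic_observations(frozen, design, noise_cv=0.0)
        refit = pf.fit_loglog(synth)
        assert refit.coefficients == pytest.approx(pf.FROZEN_COEFFICIENTS, abs=1e-10)

    def test_matches_normal_equations_oracle(self, packaged_table):
        X, y = _table_xy(packaged_table, "ca_eft")
        A = np.column_stack([np.ones(len(y)), np.log(X)])
        beta = np.linalg.solve(A.T @ A, A.T @ np.log(y))
        model = pf.fit_loglog(packaged_table)
        assert model.coefficients == pytest.approx(tuple(beta), abs=1e-9)

    def test_refit_on_study_data_has_published_sign_pattern(self, packaged_table):
        c0, c1, c2, c3 = pf.fit_loglog(packaged_table).coefficients
        assert c1 < 0 and c2 < 0 and c3 > 0

    def test_single_phase_duration_is_degenerate(self, frozen):
        design = [pf.PulseTrain(p, 1.0, f) for p in (50, 100, 200) for f in (2, 20)]
        synth = pf.generate_synthetic_observations(frozen, design, noise_cv=0.0)
        with pytest.raises(DegenerateDesignError, match="phase_duration"):
            pf.fit_loglog(synth)

    def test_too_few_records_rejected(self, frozen):
        design = [pf.PulseTrain(50, 0.2, 2), pf.PulseTrain(100, 1, 20)]
        synth = pf.generate_synthetic_observations(frozen, design, noise_cv=0.0)
        with pytest.raises(ValueError, match="at least 5"):
            pf.fit_loglog(synth)

    def test_noisy_recovery_within_three_sd(self, frozen, packaged_table):
        """Monte-Carlo: mean fitted coefficients track the generating values."""
        design = [r.train for r in packaged_table]
        fits = []
        for seed in range(20):
            synth = pf.generate_synthetic_observations(
                frozen, design, noise_cv=0.1, seed=seed
            )
            fits.append(pf.fit_loglog(synth).coefficients)
        fits = np.asarray(fits)
        mean = fits.mean(axis=0)
        sd = fits.std(axis=0, ddof=1)
        assert np.all(np.abs(mean - np.asarray(pf.FROZEN_COEFFICIENTS)) <= 3 * sd)


class TestCrossValidation:
    def test_folds_partition_all_indices(self, packaged_table):
        report = pf.cross_validate(packaged_table, k=10, seed=0)
        indices = sorted(i for fold in report.fold_assignments for i in fold)
        assert indices == list(range(len(packaged_table)))
        sizes = [len(f) for f in report.fold_assignments]
        assert max(sizes) - min(sizes) <= 1

    def test_same_seed_gives_identical_folds(self, packaged_table):
        a = pf.cross_validate(packaged_table, k=10, seed=3)
        b = pf.cross_validate(packaged_table, k=10, seed=3)
        assert a.fold_assignments == b.fold_assignments
        assert a.r2_test_mean == b.r2_test_mean

    def test_noiseless_table_scores_perfectly(self, frozen, packaged_table):
        design = [r.train for r in packaged_table]
        synth = pf.generate_synthetic_observations(frozen, design, noise_cv=0.0)
        report = pf.cross_validate(synth, k=10, seed=0)
        assert report.r2_train_mean == pytest.approx(1.0, abs=1e-12)
        assert report.r2_test_mean == pytest.approx(1.0, abs=1e-12)

    def test_k_below_two_rejected(self, packaged_table):
        with pytest.raises(ValueError):
            pf.cross_validate(packaged_table, k=1)

    def test_k_above_record_count_rejected(self, packaged_table):
        with pytest.raises(ValueError):
            pf.cross_validate(packaged_table, k=53)


class TestResidualDiagnostics:
    def test_study_data_max_relative_error_below_band(self, frozen, packaged_table):
        report = pf.residual_diagnostics(frozen, packaged_table)
        assert report.max_rel_err <= 0.33

    def test_max_fields_are_maxima_of_lists(self, frozen, packaged_table):
        report = pf.residual_diagnostics(frozen, packaged_table)
        assert report.max_abs_err == pytest.approx(report.absolute_errors.max())
        assert report.max_rel_err == pytest.approx(report.relative_errors.max())

    def test_self_evaluation_has_zero_error(self, frozen, packaged_table):
        design = [r.train for r in packaged_table]
        synth = pf.generate_synthetic_observations(frozen, design, noise_cv=0.0)
        report = pf.residual_diagnostics(frozen, synth)
        assert report.max_abs_err == pytest.approx(0.0, abs=1e-12)

    def test_correlation_sign_pattern(self, frozen, packaged_table):
        report = pf.residual_diagnostics(frozen, packaged_table)
        assert report.corr_tp < 0
        assert report.corr_pnum < 0
        assert report.corr_prf > 0

    def test_empty_table_rejected(self, frozen):
        with pytest.raises(ValueError):
            pf.residual_diagnostics(frozen, pf.ObservationTable())
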