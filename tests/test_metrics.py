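"""Agreement metrics, CRPS, folds and cross-validation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import adpkdval as av
from adpkdval.metrics import (
    MetricError,
    R2_PEARSON,
    R2_SSE,
    bland_altman_frame,
    validation_report,
)


class TestBiasAndLoa:
    def test_perfect_agreement(self):
        assert av.bias_and_loa([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == (0.0, 0.0, 0.0)

    def test_hand_computed_three_points(self):
        # diffs -2, 2, -3: mean -1, sd sqrt(7)
        bias, lo, hi = av.bias_and_loa([10, 20, 30], [12, 18, 33])
        assert bias == pytest.approx(-1.0)
        assert lo == pytest.approx(-1 - 1.96 * np.sqrt(7), abs=1e-9)
        assert (lo, hi) == (pytest.approx(-6.186, abs=1e-3), pytest.approx(4.186, abs=1e-3))

    def test_hand_computed_symmetric_pair(self):
        bias, lo, hi = av.bias_and_loa([100, 100], [70, 130])
        assert bias == 0.0
        assert hi == pytest.approx(1.96 * 30 * np.sqrt(2), abs=1e-9)
        assert (lo, hi) == (pytest.approx(-83.156, abs=1e-2), pytest.approx(83.156, abs=1e-2))

    def test_requires_two_pairs(self):
        with pytest.raises(MetricError):
            av.bias_and_loa([1.0], [1.0])

    @given(
        st.lists(st.tuples(st.floats(10, 150), st.floats(10, 150)), min_size=2, max_size=30)
    )
    @settings(max_examples=100, deadline=None)
    def test_loa_identity_and_permutation_invariance(self, pairs):
        obs = np.array([p[0] for p in pairs])
        pred = np.array([p[1] for p in pairs])
        bias, lo, hi = av.bias_and_loa(obs, pred)
        sd = np.std(obs - pred, ddof=1)
        assert lo == pytest.approx(bias - 1.96 * sd, abs=1e-12)
        assert hi == pytest.approx(bias + 1.96 * sd, abs=1e-12)
        perm = np.random.default_rng(0).permutation(len(obs))
        assert av.bias_and_loa(obs[perm], pred[perm])[0] == pytest.approx(bias, abs=1e-12)


class TestP30:
    def test_exact_predictions(self):
        assert av.p30([50.0, 60.0], [50.0, 60.0]) == 100.0

    def test_half_within_band(self):
        assert av.p30([100, 100, 100, 100], [129, 131, 71, 69]) == 50.0

    def test_boundary_inclusive(self):
        assert av.p30([100.0], [130.0]) == 100.0
        assert av.p30([100.0], [70.0]) == 100.0

    def test_rejects_nonpositive_observed(self):
        with pytest.raises(MetricError):
            av.p30([0.0, 50.0], [10.0, 50.0])


class TestRSquared:
    def test_perfect_fit_both_variants(self):
        obs = [10.0, 20.0, 30.0]
        assert av.r_squared(obs, obs, R2_SSE) == 1.0
        assert av.r_squared(obs, obs, R2_PEARSON) == pytest.approx(1.0)

    def test_null_model_gives_zero(self):
        obs = np.array([10.0, 20.0, 30.0])
        pred = np.full(3, obs.mean())
        assert av.r_squared(obs, pred, R2_SSE) == pytest.approx(0.0)

    def test_matches_independent_formula(self, rng):
        for _ in range(20):
            obs = rng.normal(80, 15, size=12)
            pred = obs + rng.normal(0, 5, size=12)
            direct = 1 - ((obs - pred) ** 2).sum() / ((obs - obs.mean()) ** 2).sum()
            assert av.r_squared(obs, pred, R2_SSE) == pytest.approx(direct, abs=1e-12)
            r = np.corrcoef(obs, pred)[0, 1]
            assert av.r_squared(obs, pred, R2_PEARSON) == pytest.approx(r ** 2, abs=1e-12)

    def test_constant_observations_rejected(self):
        with pytest.raises(MetricError):
            av.r_squared([5.0, 5.0], [4.0, 6.0])


class TestAic:
    def test_arithmetic(self):
        assert av.aic(0.0, 1) == 2.0
        assert av.aic(-100.0, 5) == 210.0

    def test_matches_statsmodels_on_a_refit(self, small_cohort):
        # cross-check oracle: ML fit AIC with fixed effects + 2 variance
        # components counted as parameters
        fitted = av.fit_development_model(small_cohort, av.MODE_CONTINUOUS)
        k = len(fitted.beta) + 2
        assert av.aic(fitted.loglik, k) == pytest.approx(-2 * fitted.loglik + 2 * k, abs=1e-9)


class TestCrps:
    def test_degenerate_point_forecast(self):
        assert av.crps_normal(5.0, 0.0, 3.0) == 2.0

    def test_centered_unit_normal_closed_form(self):
        # sigma * (2*phi(0) - 1/sqrt(pi)) at z = 0
        assert av.crps_normal(1.0, 1.0, 1.0) == pytest.approx(0.23370, abs=1e-5)

    def test_unit_offset_closed_form(self):
        assert av.crps_normal(0.0, 1.0, 1.0) == pytest.approx(0.60244, abs=1e-5)

    def test_sample_crps_enumerated_pairs(self):
        # {0, 2} vs y=1: mean|X-y| = 1, mean pairwise |diff| over the 4
        # ordered pairs = 1, so CRPS = 1 - 0.5
        assert av.crps_sample([0.0, 2.0], 1.0) == pytest.approx(0.5, abs=1e-12)

    def test_sample_equals_outcome_scores_zero(self):
        assert av.crps_sample([3.0, 3.0, 3.0], 3.0) == 0.0

    def test_sample_matches_quadratic_enumeration(self, rng):
        # independent O(n^2) oracle on small samples
        for _ in range(10):
            x = rng.normal(0, 2, size=25)
            y = float(rng.normal())
            pair = np.abs(x[:, None] - x[None, :]).mean()
            direct = np.abs(x - y).mean() - 0.5 * pair
            assert av.crps_sample(x, y) == pytest.approx(direct, abs=1e-12)

    def test_normal_properties(self):
        assert av.crps_normal(0.0, 1.0, 0.5) > 0
        # strictly increasing in |y - mu| for fixed sigma
        vals = [av.crps_normal(0.0, 1.0, y) for y in (0.0, 0.5, 1.0, 2.0)]
        assert vals == sorted(vals)

    def test_mean_crps_homogeneous_sigma(self):
        import pandas as pd

        frame = pd.DataFrame(
            {"egfr_pred": [80.0, 90.0], "pred_sd": [3.0, 3.0], "egfr_obs": [80.0, 90.0]}
        )
        assert av.mean_crps(frame) == pytest.approx(0.23370 * 3.0, abs=1e-4)

    def test_mean_crps_requires_pred_sd(self):
        import pandas as pd

        frame = pd.DataFrame({"egfr_pred": [80.0], "egfr_obs": [80.0]})
        with pytest.raises(MetricError, match="predictive SD"):
            av.mean_crps(frame)


class TestFolds:
    def test_even_split(self, small_cohort):
        folds = av.make_folds(small_cohort, k=5, seed=1)
        sizes = sorted(len(folds.fold_patients(i)) for i in range(5))
        assert sizes == [16, 16, 16, 16, 16]

    def test_remainder_rule(self):
        cohort = av.generate_cohort(av.GeneratorConfig(n_patients=11, seed=6))
        folds = av.make_folds(cohort, k=5, seed=1)
        sizes = sorted((len(folds.fold_patients(i)) for i in range(5)), reverse=True)
        assert sizes == [3, 2, 2, 2, 2]

    def test_deterministic_under_seed(self, small_cohort):
        a = av.make_folds(small_cohort, k=5, seed=42)
        b = av.make_folds(small_cohort, k=5, seed=42)
        assert a.assignment == b.assignment

    def test_too_few_patients(self):
        cohort = av.generate_cohort(av.GeneratorConfig(n_patients=3, seed=1))
        with pytest.raises(MetricError):
            av.make_folds(cohort, k=5)


class TestCrossValidation:
    def test_leave_one_patient_out_runs(self, truth):
        cohort = av.generate_cohort(av.GeneratorConfig(n_patients=10, seed=14, missing_rate=0.0))
        report = av.cross_validated_report(cohort, truth, av.UPDATE_MODEL2, k=10, seed=0)
        assert report.n_obs == cohort.n_visits

    def test_report_carries_loa_identity(self, truth, small_cohort):
        report = av.cross_validated_report(small_cohort, truth, av.UPDATE_MODEL1, seed=3)
        sd = (report.loa_high - report.bias) / 1.96
        assert report.loa_low == pytest.approx(report.bias - 1.96 * sd, abs=1e-9)
        assert 0 <= report.p30 <= 100
        assert -1 <= report.correlation <= 1


class TestValidationReport:
    def test_report_row_fields(self, rng):
        obs = rng.normal(80, 15, 50)
        pred = obs + rng.normal(0, 5, 50)
        report = validation_report("demo", obs, pred, pred_sd=np.full(50, 5.0))
        row = report.to_row()
        assert row["model"] == "demo" and row["n_obs"] == 50
        assert row["crps"] is not None and row["aic"] is None

    def test_bland_altman_frame_columns(self):
        frame = bland_altman_frame([100.0, 90.0], [95.0, 92.0])
        assert list(frame.columns) == ["mean", "diff"]
        assert frame["diff"].tolist() == [5.0, -2.0]
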