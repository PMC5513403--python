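"""Mixed-model fitting, prediction and partial coefficient updating."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import adpkdval as av
from adpkdval.model import (
    MODE_CONTINUOUS,
    MODE_RISK_CLASS,
    ModelError,
    design_row,
    free_update_terms,
    terms_for_mode,
    update_design,
)


class TestDesignRow:
    BASE = {"httkv0": 512.0, "age0": 40.0, "sex": "female", "egfr0": 82.0}

    def test_interactions_vanish_at_t0(self):
        row = design_row(self.BASE, 0.0, MODE_CONTINUOUS)
        assert all(v == 0.0 for k, v in row.items() if k.startswith("t:"))
        assert row["t"] == 0.0

    def test_power_of_two_httkv(self):
        assert design_row(self.BASE, 1.0, MODE_CONTINUOUS)["log2_httkv"] == 9.0

    def test_class_mode_reference_level(self):
        # httkv0 150 at any age implies zero growth: class 1A, the reference
        base = dict(self.BASE, httkv0=150.0)
        row = design_row(base, 2.0, MODE_RISK_CLASS)
        assert all(row[f"class_{c}"] == 0.0 for c in ("1B", "1C", "1D", "1E"))

    def test_interaction_values_scale_with_t(self):
        row = design_row(self.BASE, 3.0, MODE_CONTINUOUS)
        assert row["t:age0"] == pytest.approx(3.0 * 40.0)
        assert row["t:log2_httkv"] == pytest.approx(3.0 * 9.0)
        assert row["t:sex"] == pytest.approx(3.0)

    def test_missing_httkv_rejected_in_continuous_mode(self):
        with pytest.raises(ModelError):
            design_row(dict(self.BASE, httkv0=None), 1.0, MODE_CONTINUOUS)


class TestPrediction:
    def test_intercept_only_model(self, truth):
        coeffs = av.ModelCoefficients(
            mode=MODE_CONTINUOUS,
            beta={t: (50.0 if t == "intercept" else 0.0) for t in terms_for_mode(MODE_CONTINUOUS)},
            var_random_slope=0.0,
            var_residual=4.0,
        )
        rec = av.predict_egfr(coeffs, TestDesignRow.BASE, 0.0)
        assert rec.egfr_pred == 50.0
        assert rec.pred_sd == 2.0  # sqrt(var_residual) at any t when slope var is 0

    def test_matches_independent_dot_product(self, rng, truth):
        # brute-force oracle: recompute the linear predictor by hand
        for _ in range(10):
            base = {
                "httkv0": rng.uniform(200, 2000),
                "age0": rng.uniform(20, 60),
                "sex": rng.choice(["female", "male"]),
                "egfr0": rng.uniform(40, 110),
            }
            t = rng.uniform(0, 10)
            rec = av.predict_egfr(truth, base, t)
            l2 = np.log2(base["httkv0"])
            sexnum = 1.0 if base["sex"] == "female" else 0.0
            b = truth.beta
            expected = (
                b["intercept"] + b["log2_httkv"] * l2 + b["age0"] * base["age0"]
                + b["sex"] * sexnum + b["egfr0"] * base["egfr0"] + b["t"] * t
                + b["t:log2_httkv"] * t * l2 + b["t:age0"] * t * base["age0"]
                + b["t:sex"] * t * sexnum + b["t:egfr0"] * t * base["egfr0"]
            )
            assert rec.egfr_pred == pytest.approx(expected, abs=1e-10)

    def test_predictive_sd_non_decreasing_in_t(self, truth):
        sds = [av.predict_egfr(truth, TestDesignRow.BASE, t).pred_sd for t in (0, 1, 5, 10)]
        assert sds == sorted(sds)
        assert sds[0] == pytest.approx(np.sqrt(truth.var_residual))

    def test_negative_time_rejected(self, truth):
        with pytest.raises(ModelError):
            av.predict_egfr(truth, TestDesignRow.BASE, -1.0)

    def test_doubling_httkv_shifts_by_coefficients(self, truth):
        # linearity in log2 HtTKV: doubling adds beta_httkv + t * beta_t:httkv
        t = 4.0
        a = av.predict_egfr(truth, TestDesignRow.BASE, t).egfr_pred
        b = av.predict_egfr(truth, dict(TestDesignRow.BASE, httkv0=1024.0), t).egfr_pred
        expected = truth.beta["log2_httkv"] + t * truth.beta["t:log2_httkv"]
        assert b - a == pytest.approx(expected, abs=1e-10)


class TestFit:
    def test_noiseless_recovery(self, noiseless_cohort):
        truth = av.noiseless_config(40).egfr_model_truth
        fitted = av.fit_development_model(noiseless_cohort, MODE_CONTINUOUS)
        for term, value in truth.beta.items():
            assert fitted.beta[term] == pytest.approx(value, abs=1e-6)

    def test_fit_is_deterministic(self, small_cohort):
        a = av.fit_development_model(small_cohort, MODE_CONTINUOUS)
        b = av.fit_development_model(small_cohort, MODE_CONTINUOUS)
        assert a.beta == b.beta
        assert a.var_random_slope == b.var_random_slope

    def test_single_sex_design_raises_informative_error(self):
        cohort = av.generate_cohort(av.GeneratorConfig(n_patients=40, seed=2, frac_female=1.0))
        with pytest.raises(ModelError, match="singular"):
            av.fit_development_model(cohort, MODE_CONTINUOUS)

    def test_risk_class_mode_fits(self, small_cohort):
        fitted = av.fit_development_model(small_cohort, MODE_RISK_CLASS)
        assert set(fitted.beta) == set(terms_for_mode(MODE_RISK_CLASS))
        assert fitted.var_residual > 0

    def test_coefficients_json_round_trip(self, small_cohort, tmp_path):
        fitted = av.fit_development_model(small_cohort, MODE_CONTINUOUS)
        path = tmp_path / "coeffs.json"
        fitted.to_json(path)
        back = av.ModelCoefficients.from_json(path)
        assert back.beta == fitted.beta
        assert back.var_random_slope == fitted.var_random_slope


class TestPartialUpdate:
    def test_self_consistency_on_noiseless_data(self):
        # data generated exactly from the frozen coefficients, with constant
        # HtTKV so the time-varying covariate equals the baseline one
        cfg = replace(
            av.noiseless_config(60, seed=21),
            growth_rate_dist=(0.0, 1e-9), growth_rate_bias=0.0,
        )
        cohort = av.generate_cohort(cfg)
        truth = cfg.egfr_model_truth
        updated = av.partial_update(truth, cohort, av.UPDATE_MODEL2)
        assert updated.beta["log2_httkv"] == pytest.approx(truth.beta["log2_httkv"], abs=1e-6)

    def test_frozen_terms_bit_unchanged(self, truth, small_cohort):
        for mode, with_int in [
            (av.UPDATE_MODEL1, False), (av.UPDATE_MODEL1, True),
            (av.UPDATE_MODEL2, False), (av.UPDATE_MODEL2, True),
        ]:
            updated = av.partial_update(truth, small_cohort, mode, with_int)
            free = free_update_terms(mode, with_int)
            for term, value in truth.beta.items():
                if term not in free:
                    assert updated.beta[term] == value  # exact, not approx

    def test_update_requires_continuous_mode(self, small_cohort):
        class_fit = av.fit_development_model(small_cohort, MODE_RISK_CLASS)
        with pytest.raises(ModelError, match="continuous"):
            av.partial_update(class_fit, small_cohort, av.UPDATE_MODEL2)

    def test_model1_requires_a_second_measurement(self, truth, small_cohort):
        bare = small_cohort.copy()
        bare.visits["httkv"] = np.nan
        with pytest.raises(ModelError, match="non-missing"):
            av.partial_update(truth, bare, av.UPDATE_MODEL1)

    def test_model2_excludes_missing_visits(self, small_cohort):
        dm = update_design(small_cohort, av.UPDATE_MODEL2)
        assert len(dm) == small_cohort.visits["httkv"].notna().sum()

    def test_model1_keeps_all_visits_of_measured_patients(self, small_cohort):
        dm = update_design(small_cohort, av.UPDATE_MODEL1)
        measured = small_cohort.visits.dropna(subset=["httkv"])["patient_id"].unique()
        expected = small_cohort.visits["patient_id"].isin(measured).sum()
        assert len(dm) == expected
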