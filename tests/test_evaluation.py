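import numpy as np
import pytest
from scipy.stats import mannwhitneyu

import bioage as ba

from conftest import bare_gompertz_fit, make_cohort


class TestLifeExpectancy:
    def test_quadrature_matches_brute_force_trapezoid(self):
        fit = bare_gompertz_fit(1e-5, 0.1, coef={"delta_ba": 0.0})
        e = ba.life_expectancy(fit, age=65.0, delta=0.0, phi_name="delta_ba")
        t = np.arange(0.0, 55.0 + 0.001, 0.001)
        a = (fit.k / fit.beta) * np.exp(fit.beta * 65.0)
        s = np.exp(-a * np.expm1(fit.beta * t))
        brute = np.trapezoid(s, t)
        assert e == pytest.approx(brute, abs=1e-4)

    def test_quadrature_matches_exponential_integral_closed_form(self):
        fit = bare_gompertz_fit(2e-4, 0.09, coef={"delta_ba": 0.1})
        for delta in (-5.0, 0.0, 5.0):
            q = ba.life_expectancy(fit, 65.0, delta, "delta_ba")
            c = ba.life_expectancy_closed_form(fit, 65.0, delta, "delta_ba")
            assert q == pytest.approx(c, abs=1e-6)

    def test_positive_phi_orders_scenarios(self):
        fit = bare_gompertz_fit(1e-4, 0.09, coef={"delta_ba": 0.1})
        older = ba.life_expectancy(fit, 65.0, 5.0, "delta_ba")
        base = ba.life_expectancy(fit, 65.0, 0.0, "delta_ba")
        younger = ba.life_expectancy(fit, 65.0, -5.0, "delta_ba")
        assert older < base < younger


class TestE65Curve:
    def test_zero_phi_gives_flat_differences(self):
        fit = bare_gompertz_fit(1e-4, 0.09, coef={"delta_ba": 0.0})
        curve = ba.e65_delta_curve(fit, phi_name="delta_ba")
        np.testing.assert_allclose(curve["diff_vs_zero"], 0.0, atol=1e-10)

    def test_differences_fall_in_the_opposite_quadrants(self):
        fit = bare_gompertz_fit(1e-4, 0.09, coef={"delta_ba": 0.1})
        curve = ba.e65_delta_curve(fit, phi_name="delta_ba")
        nz = curve[curve["delta"] != 0]
        assert np.all(np.sign(nz["diff_vs_zero"]) == -np.sign(nz["delta"]))

    def test_steeper_phi_gives_uniformly_larger_changes(self):
        shallow = bare_gompertz_fit(1e-4, 0.09, coef={"delta_ba": 0.03})
        steep = bare_gompertz_fit(1e-4, 0.09, coef={"delta_ba": 0.25})
        cs = ba.e65_delta_curve(shallow, phi_name="delta_ba")
        ct = ba.e65_delta_curve(steep, phi_name="delta_ba")
        nz = cs["delta"] != 0
        assert np.all(
            np.abs(ct["diff_vs_zero"][nz].to_numpy())
            > np.abs(cs["diff_vs_zero"][nz].to_numpy())
        )


class TestROCAUC:
    def test_perfect_separation_scores_one_on_any_band(self):
        scores = np.concatenate([np.zeros(50), np.ones(50)])
        labels = np.concatenate([np.zeros(50, int), np.ones(50, int)])
        for band in ((0.0, 1.0), (0.8, 0.9), (0.9, 1.0)):
            assert ba.roc_auc(scores, labels, band) == pytest.approx(1.0)

    def test_independent_scores_give_half(self):
        rng = np.random.default_rng(10)
        scores = rng.normal(size=10000)
        labels = rng.integers(0, 2, size=10000)
        assert abs(ba.roc_auc(scores, labels) - 0.5) < 0.02

    def test_full_auc_equals_mann_whitney_statistic(self):
        rng = np.random.default_rng(11)
        scores = rng.normal(size=400) + np.concatenate([np.zeros(200), 0.7 * np.ones(200)])
        labels = np.concatenate([np.zeros(200, int), np.ones(200, int)])
        u = mannwhitneyu(scores[labels == 1], scores[labels == 0]).statistic
        assert ba.roc_auc(scores, labels) == pytest.approx(u / (200 * 200), abs=1e-12)

    def test_midrank_tie_handling_matches_mann_whitney(self):
        scores = np.array([0, 1, 1, 1, 2, 2, 3, 3], dtype=float)
        labels = np.array([0, 0, 1, 0, 1, 0, 1, 1])
        u = mannwhitneyu(scores[labels == 1], scores[labels == 0]).statistic
        assert ba.roc_auc(scores, labels) == pytest.approx(u / 16.0, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ba.roc_auc([1.0, 2.0], [1, 1])

    def test_horizon_labels_drop_early_censored(self, cohort, null_fit):
        scores, labels = ba.roc_inputs_at_horizon(cohort, null_fit, 20.0)
        early_censored = ((cohort.dead == 0) & (cohort.duration < 20.0)).sum()
        assert len(scores) == cohort.n - early_censored
        assert set(np.unique(labels)) == {0, 1}


class TestBACARegression:
    def test_identity_ba_gives_exact_line(self, cohort):
        est = ba.BAEstimates("KD", cohort.age.copy(), cohort.age)
        reg = ba.ba_ca_regression(est, cohort)
        assert reg.slope == pytest.approx(1.0, abs=1e-12)
        assert reg.intercept == pytest.approx(0.0, abs=1e-9)

    def test_mlr_slope_equals_r2_oracle(self, cohort):
        est = ba.estimate_mlr(cohort)
        reg = ba.ba_ca_regression(est, cohort)
        mlr = ba.MLRAge().fit(cohort.marker_frame, cohort.age)
        assert reg.slope == pytest.approx(mlr.r2_, abs=1e-10)

    def test_kd_fails_to_reject_identity_line_across_seeds(self):
        # the corrected KD estimator satisfies (0, 1) as an in-sample
        # identity, so the Wald battery should essentially never reject
        hits = 0
        for seed in range(50):
            c, _ = ba.simulate_cohort(ba.default_truth(seed=400 + seed, n=400))
            est = ba.estimate_kd(c, ba.kd_calibrate(c))
            reg = ba.ba_ca_regression(est, c)
            if reg.p_intercept_zero > 0.05 and reg.p_slope_one > 0.05:
                hits += 1
        assert hits >= 45


class TestDisparityRegression:
    def test_injected_group_offset_recovered(self):
        t = ba.default_truth(
            seed=77, n=6000, covariate_effects={"race": {"nh_black": 2.0}}
        )
        c, _ = ba.simulate_cohort(t)
        est = ba.estimate_kd(c, ba.kd_calibrate(c))
        table = ba.disparity_regression(est, c)
        coef = table.loc["nh_black", "KD"]
        # SE of a group contrast on ~13 y BA noise at this group size
        assert coef == pytest.approx(2.0, abs=1.2)
        assert table.loc["p_nh_black", "KD"] < 0.05

    def test_no_injected_effects_give_null_coefficients(self, cohort):
        est = ba.estimate_kd(cohort, ba.kd_calibrate(cohort))
        table = ba.disparity_regression(est, cohort)
        for term in ("female", "nh_black", "mex_american", "hs", "college_plus"):
            assert abs(table.loc[term, "KD"]) < 1.5

    def test_column_order_follows_method_convention(self, cohort, fs_linear):
        kd = ba.estimate_kd(cohort, ba.kd_calibrate(cohort))
        mlr = ba.estimate_mlr(cohort)
        of, _ = ba.estimate_of(fs_linear, cohort, "linear")
        table = ba.disparity_regression([of, mlr, kd], cohort)
        assert list(table.columns) == ["KD", "MLR", "OF-linear"]

    def test_missing_reference_level_rejected(self):
        c = make_cohort(
            age=[50.0, 60.0, 55.0, 65.0],
            markers={"m": [1.0, 2.0, 3.0, 4.0]},
            covariates={
                "sex": ["female", "male", "female", "male"],
                "race": ["nh_black", "nh_black", "mex_american", "nh_black"],
                "education": ["hs", "hs", "less_than_hs", "hs"],
            },
        )
        est = ba.BAEstimates("KD", c.age + 1.0, c.age)
        with pytest.raises(ValueError, match="nh_white"):
            ba.disparity_regression(est, c)
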