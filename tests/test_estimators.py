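import numpy as np
import pytest

import bioage as ba
from bioage.estimators import DegenerateMarkerError

from conftest import make_cohort


def _ols_slope_intercept(x, y):
    """Independent normal-equations solve (the oracle for slope checks)."""
    X = np.column_stack([np.ones(len(x)), x])
    coef = np.linalg.solve(X.T @ X, X.T @ y)
    return coef[1], coef[0]


class TestMLR:
    def test_noise_free_markers_reproduce_ca_exactly(self):
        rng = np.random.default_rng(0)
        age = rng.uniform(30, 75, 100)
        # second marker adds an independent direction so the design stays
        # full rank while CA remains perfectly recoverable from marker 1
        c = make_cohort(
            age=age, markers={"m1": 2 * age + 1, "m2": rng.normal(size=100)}
        )
        est = ba.estimate_mlr(c)
        np.testing.assert_allclose(est.ba, age, atol=1e-10)

    def test_slope_of_ba_on_ca_equals_r_squared(self, cohort):
        est = ba.estimate_mlr(cohort)
        slope, _ = _ols_slope_intercept(cohort.age, est.ba)
        mlr = ba.MLRAge().fit(cohort.marker_frame, cohort.age)
        assert slope == pytest.approx(mlr.r2_, abs=1e-10)

    def test_ba_positively_correlated_with_ca(self, cohort):
        est = ba.estimate_mlr(cohort)
        assert np.corrcoef(est.ba, cohort.age)[0, 1] > 0

    def test_collinear_markers_rejected(self):
        rng = np.random.default_rng(1)
        age = rng.uniform(30, 75, 50)
        m = rng.normal(size=50)
        c = make_cohort(age=age, markers={"m1": m, "m2": 2 * m})
        with pytest.raises(ValueError, match="rank"):
            ba.estimate_mlr(c)


class TestPCA:
    def test_two_identical_markers_give_full_first_component(self):
        rng = np.random.default_rng(2)
        age = rng.uniform(30, 75, 200)
        m = rng.normal(size=200)
        c = make_cohort(age=age, markers={"m1": m, "m2": 3 * m + 1})
        est = ba.PCAAge().fit(c.marker_frame, c.age)
        assert est.explained_variance_ratio_ == pytest.approx(1.0, abs=1e-12)

    def test_ba_matches_ca_moments_by_construction(self, cohort):
        est = ba.estimate_pca(cohort)
        assert est.ba.mean() == pytest.approx(cohort.age.mean(), abs=1e-10)
        assert est.ba.std(ddof=1) == pytest.approx(cohort.age.std(ddof=1), abs=1e-10)

    def test_two_marker_toy_matches_hand_eigenvector(self):
        # 4 subjects, 2 markers; correlation matrix [[1, r], [r, 1]] has
        # leading eigenvector (1, 1)/sqrt(2) for r > 0 by the quadratic formula
        age = np.array([40.0, 50.0, 60.0, 70.0])
        m1 = np.array([0.0, 1.0, 2.0, 5.0])
        m2 = np.array([1.0, 2.0, 4.0, 7.0])
        c = make_cohort(age=age, markers={"m1": m1, "m2": m2})
        z1 = (m1 - m1.mean()) / m1.std(ddof=1)
        z2 = (m2 - m2.mean()) / m2.std(ddof=1)
        pc = (z1 + z2) / np.sqrt(2)  # hand eigen-projection
        expected = age.mean() + (pc - pc.mean()) / pc.std(ddof=1) * age.std(ddof=1)
        est = ba.estimate_pca(c)
        np.testing.assert_allclose(est.ba, expected, atol=1e-10)

    def test_invariant_to_marker_order_and_sign_flip(self, cohort):
        base = ba.estimate_pca(cohort)
        df = cohort.data.copy()
        flipped = list(cohort.markers[::-1])
        df[flipped[0]] = -df[flipped[0]]
        c2 = ba.Cohort(df[[*df.columns]], flipped, list(cohort.covariates))
        again = ba.estimate_pca(c2)
        np.testing.assert_allclose(again.ba, base.ba, atol=1e-8)


class TestKDCalibration:
    def test_exact_linear_marker_triggers_degenerate_guard(self):
        rng = np.random.default_rng(3)
        age = rng.uniform(30, 75, 100)
        c = make_cohort(
            age=age,
            markers={"m1": 0.5 * age + 10, "m2": rng.normal(age, 5)},
        )
        with pytest.raises(DegenerateMarkerError, match="m1"):
            ba.kd_calibrate(c)

    def test_per_marker_regression_parameters(self):
        rng = np.random.default_rng(4)
        age = rng.uniform(30, 75, 2000)
        c = make_cohort(
            age=age,
            markers={"m1": 0.5 * age + 10 + rng.normal(0, 1, 2000), "m2": rng.normal(age, 5)},
        )
        cal = ba.kd_calibrate(c)
        assert cal.slopes[0] == pytest.approx(0.5, abs=0.01)
        assert cal.intercepts[0] == pytest.approx(10.0, abs=0.6)
        assert cal.resid_sds[0] == pytest.approx(1.0, abs=0.05)

    def test_slope_signs_follow_the_generating_loadings(self, cohort, truth):
        cal = ba.kd_calibrate(cohort)
        for j in range(len(truth.loadings)):
            assert np.sign(cal.slopes[j]) == np.sign(
                truth.loadings[j] * truth.structural_slope
            )

    def test_age_subset_changes_calibration_but_stays_finite(self, cohort):
        full = ba.kd_calibrate(cohort)
        sub = cohort.subset((cohort.age >= 40) & (cohort.age <= 60))
        cal = ba.kd_calibrate(sub)
        assert np.all(np.isfinite(cal.slopes)) and cal.s_ba > 0
        assert not np.allclose(cal.intercepts, full.intercepts)

    def test_uncorrelated_marker_excluded_with_warning(self):
        age = np.tile([40.0, 50.0, 60.0, 70.0], 50)
        rng = np.random.default_rng(5)
        noise = np.tile([1.0, -1.0, -1.0, 1.0], 50)  # exactly orthogonal to age
        c = make_cohort(
            age=age, markers={"m1": rng.normal(age, 3), "m2": noise}
        )
        with pytest.warns(UserWarning, match="m2"):
            cal = ba.kd_calibrate(c)
        assert cal.included.tolist() == [True, False]


class TestKDEstimate:
    def test_single_marker_formula_collapses_to_inverse_regression(self):
        rng = np.random.default_rng(6)
        age = rng.uniform(30, 75, 200)
        c = make_cohort(age=age, markers={"m1": 0.8 * age + 5 + rng.normal(0, 2, 200)})
        cal = ba.kd_calibrate(c)
        q, k = cal.intercepts[0], cal.slopes[0]
        subject = q + k * 60.0  # marker value of a 60-year-old on the line
        ba_e = (subject - q) * (k / cal.resid_sds[0] ** 2) / (k / cal.resid_sds[0]) ** 2
        assert ba_e == pytest.approx(60.0, abs=1e-10)

    def test_three_subject_toy_matches_hand_arithmetic(self):
        age = np.array([40.0, 55.0, 70.0])
        m1 = np.array([20.0, 30.0, 34.0])
        m2 = np.array([9.0, 6.0, 2.0])
        c = make_cohort(age=age, markers={"m1": m1, "m2": m2})
        cal = ba.kd_calibrate(c)
        est = ba.estimate_kd(c, cal, corrected=False)
        q, k, s = cal.intercepts, cal.slopes, cal.resid_sds
        for i in range(3):
            num = sum((([m1, m2][j][i]) - q[j]) * k[j] / s[j] ** 2 for j in range(2))
            den = sum((k[j] / s[j]) ** 2 for j in range(2))
            assert est.ba[i] == pytest.approx(num / den, abs=1e-12)

    def test_corrected_ba_regression_on_ca_is_the_identity_line(self, cohort):
        cal = ba.kd_calibrate(cohort)
        est = ba.estimate_kd(cohort, cal)
        slope, intercept = np.polyfit(cohort.age, est.ba, 1)
        assert slope == pytest.approx(1.0, abs=1e-8)
        assert intercept == pytest.approx(0.0, abs=1e-6)

    def test_corrected_shrinks_toward_ca(self, cohort):
        cal = ba.kd_calibrate(cohort)
        raw = ba.estimate_kd(cohort, cal, corrected=False)
        cor = ba.estimate_kd(cohort, cal)
        assert np.mean(np.abs(cor.ba - cohort.age)) < np.mean(np.abs(raw.ba - cohort.age))

    def test_user_supplied_s_ba2_respected(self, cohort):
        cal = ba.kd_calibrate(cohort, s_ba2=4.0)
        assert cal.s_ba == pytest.approx(2.0)


def test_delta_is_exact_elementwise_difference(cohort):
    est = ba.estimate_mlr(cohort)
    np.testing.assert_array_equal(est.delta, est.ba - cohort.age)
    assert est.delta.mean() == pytest.approx(est.ba.mean() - cohort.age.mean(), abs=1e-12)
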