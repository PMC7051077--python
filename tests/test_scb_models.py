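"""SCB regression models, Pearson correlation and LOOCV error."""

import numpy as np
import pytest

from scbkit.colorimetry import Chromaticity, D65_Z
from scbkit.scb_models import (
    SCBJECIModel,
    SCBXYModel,
    SubjectRecord,
    fit_scb_jeci,
    fit_scb_xy,
    loocv_rmse,
    pearson_r,
    predict_scb,
)


def record(i, x, y, tsb):
    return SubjectRecord.from_chromaticity(f"s{i}", Chromaticity(x, y, 1 - x - y), tsb)


def records_from_jeci(jeci_values, tsb_values):
    # place chromaticities so that z = z_D65 - jeci, split the rest evenly
    out = []
    for i, (j, t) in enumerate(zip(jeci_values, tsb_values)):
        z = D65_Z - j
        out.append(record(i, (1 - z) / 2 + 0.001 * i, (1 - z) / 2 - 0.001 * i, t))
    return out


class TestFitJECI:
    def test_exact_line_recovers_slope_intercept(self):
        j = np.array([0.01, 0.03, 0.05, 0.07, 0.09])
        recs = records_from_jeci(j, 2000 * j + 50)
        report = fit_scb_jeci(recs)
        assert report.model.m == pytest.approx(2000, abs=1e-8)
        assert report.model.n == pytest.approx(50, abs=1e-9)
        assert report.pearson_r == pytest.approx(1.0)
        assert report.loocv_rmse == pytest.approx(0.0, abs=1e-8)

    def test_hand_points_match_normal_equations_oracle(self):
        j = np.array([0.01, 0.02, 0.04, 0.07, 0.11])
        tsb = np.array([80.0, 140.0, 150.0, 260.0, 330.0])
        report = fit_scb_jeci(records_from_jeci(j, tsb))
        # closed-form OLS, computed independently
        m = np.sum((j - j.mean()) * (tsb - tsb.mean())) / np.sum((j - j.mean()) ** 2)
        n = tsb.mean() - m * j.mean()
        assert report.model.m == pytest.approx(m, rel=1e-12)
        assert report.model.n == pytest.approx(n, rel=1e-12)

    def test_constant_jeci_is_degenerate(self):
        ch = Chromaticity(0.33, 0.34, 0.33)
        recs = [
            SubjectRecord.from_chromaticity(f"s{i}", ch, t)
            for i, t in enumerate([100, 150, 200, 250, 300])
        ]
        with pytest.raises(ValueError, match="degenerate|equal"):
            fit_scb_jeci(recs)


class TestFitXY:
    def test_exact_plane_recovered(self):
        rng = np.random.default_rng(0)
        recs = []
        for i in range(12):
            x = rng.uniform(0.30, 0.40)
            y = rng.uniform(0.30, 0.38)
            recs.append(record(i, x, y, 500 * x + 300 * y + 10))
        report = fit_scb_xy(recs)
        assert report.model.p == pytest.approx(500, abs=1e-8)
        assert report.model.q == pytest.approx(300, abs=1e-8)
        assert report.model.r_intercept == pytest.approx(10, abs=1e-8)

    def test_parameter_recovery_with_noise_within_3_se(self):
        """Known (p, q, r) plus Gaussian noise: estimates land within
        three standard errors at n = 200."""
        rng = np.random.default_rng(42)
        p_true, q_true, r_true, sigma = 5000.0, -3000.0, 200.0, 30.0
        n = 200
        x = rng.uniform(0.30, 0.40, n)
        y = rng.uniform(0.30, 0.38, n)
        tsb = np.clip(p_true * x + q_true * y + r_true + rng.normal(0, sigma, n), 0, None)
        recs = [record(i, xi, yi, ti) for i, (xi, yi, ti) in enumerate(zip(x, y, tsb))]
        report = fit_scb_xy(recs)
        A = np.column_stack([x, y, np.ones(n)])
        cov = sigma**2 * np.linalg.inv(A.T @ A)
        se = np.sqrt(np.diag(cov))
        est = np.array([report.model.p, report.model.q, report.model.r_intercept])
        assert np.all(np.abs(est - [p_true, q_true, r_true]) < 3 * se)

    def test_collinear_design_is_error(self):
        recs = [record(i, 0.3 + 0.01 * i, 0.4 - 0.01 * i, 100.0 + i) for i in range(6)]
        with pytest.raises(ValueError, match="collinear|rank"):
            fit_scb_xy(recs)


class TestPredict:
    def test_constant_model(self):
        ch = Chromaticity(0.4, 0.35, 0.25)
        assert predict_scb(SCBJECIModel(m=0, n=150), ch) == 150

    def test_xy_arithmetic(self):
        ch = Chromaticity(0.4, 0.35, 0.25)
        assert predict_scb(SCBXYModel(p=1, q=1, r_intercept=0), ch) == pytest.approx(0.75)

    def test_round_trip_on_exact_fit(self):
        j = np.array([0.01, 0.03, 0.06, 0.10])
        recs = records_from_jeci(j, 1500 * j + 80)
        model = fit_scb_jeci(recs).model
        for r in recs:
            assert predict_scb(model, r.chromaticity) == pytest.approx(r.tsb, abs=1e-8)

    def test_negative_prediction_warns_but_reports(self):
        ch = Chromaticity(0.30, 0.30, 0.40)
        with pytest.warns(UserWarning, match="negative"):
            value = predict_scb(SCBJECIModel(m=1000, n=0), ch)
        assert value < 0


class TestPearson:
    def test_perfect_positive_and_negative(self):
        a = [1.0, 2.0, 4.0, 7.0]
        r_pos, _ = pearson_r(a, [2 * v + 1 for v in a])
        r_neg, _ = pearson_r(a, [-v for v in a])
        assert r_pos == pytest.approx(1.0)
        assert r_neg == pytest.approx(-1.0)

    def test_hand_pairs_match_covariance_formula(self):
        a = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 7.0])
        b = np.array([2.0, 1.0, 4.0, 6.0, 5.0, 9.0])
        r, p = pearson_r(a, b)
        # direct formula oracle
        expected = np.sum((a - a.mean()) * (b - b.mean())) / np.sqrt(
            np.sum((a - a.mean()) ** 2) * np.sum((b - b.mean()) ** 2)
        )
        assert r == pytest.approx(expected, rel=1e-12)
        assert 0 < p < 1

    def test_affine_invariance(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=20)
        b = rng.normal(size=20)
        r0, _ = pearson_r(a, b)
        r1, _ = pearson_r(3.5 * a + 2.0, 0.1 * b - 7.0)
        assert r1 == pytest.approx(r0, abs=1e-12)

    def test_zero_variance_is_error(self):
        with pytest.raises(ValueError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestLOOCV:
    def test_exact_linear_data_has_zero_error(self):
        j = np.array([0.01, 0.03, 0.05, 0.08])
        recs = records_from_jeci(j, 1000 * j + 40)
        assert loocv_rmse(recs, "jeci") == pytest.approx(0.0, abs=1e-9)

    def test_matches_fold_by_fold_brute_force(self):
        """n = 5 dataset checked against an explicit per-fold OLS oracle
        written out longhand."""
        j = np.array([0.010, 0.025, 0.050, 0.070, 0.110])
        tsb = np.array([90.0, 130.0, 180.0, 270.0, 310.0])
        recs = records_from_jeci(j, tsb)
        errors = []
        for i in range(5):
            keep = np.arange(5) != i
            jk, tk = j[keep], tsb[keep]
            m = np.sum((jk - jk.mean()) * (tk - tk.mean())) / np.sum((jk - jk.mean()) ** 2)
            n0 = tk.mean() - m * jk.mean()
            errors.append(m * j[i] + n0 - tsb[i])
        expected = np.sqrt(np.mean(np.square(errors)))
        assert loocv_rmse(recs, "jeci") == pytest.approx(expected, abs=1e-9)

    def test_xy_family_matches_brute_force(self):
        rng = np.random.default_rng(9)
        recs = [
            record(i, x, y, 400 * x + 250 * y + rng.normal(0, 20))
            for i, (x, y) in enumerate(
                zip(rng.uniform(0.3, 0.4, 6), rng.uniform(0.3, 0.38, 6))
            )
        ]
        x = np.array([r.chromaticity.x for r in recs])
        y = np.array([r.chromaticity.y for r in recs])
        tsb = np.array([r.tsb for r in recs])
        errors = []
        for i in range(6):
            keep = np.arange(6) != i
            A = np.column_stack([x[keep], y[keep], np.ones(5)])
            coef = np.linalg.solve(A.T @ A, A.T @ tsb[keep])
            errors.append(coef @ [x[i], y[i], 1.0] - tsb[i])
        expected = np.sqrt(np.mean(np.square(errors)))
        assert loocv_rmse(recs, "xy") == pytest.approx(expected, abs=1e-9)

    def test_loocv_at_least_in_sample_rmse(self):
        """OLS optimism: held-out error cannot beat training error."""
        rng = np.random.default_rng(21)
        j = rng.uniform(0.0, 0.12, 40)
        tsb = 2000 * j + 60 + rng.normal(0, 35, 40)
        recs = records_from_jeci(j, np.clip(tsb, 0, None))
        report = fit_scb_jeci(recs)
        pred = report.model.m * j + report.model.n
        in_sample = np.sqrt(np.mean((pred - np.array([r.tsb for r in recs])) ** 2))
        assert report.loocv_rmse >= in_sample
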