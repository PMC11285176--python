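import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu, norm
from sklearn.metrics import roc_auc_score

from frocdwi import (bootstrap_calibration, build_nomogram, combined_roc,
                     decision_curve, delong_test, fit_logistic_with_selection,
                     hosmer_lemeshow, roc_analysis)
from frocdwi.diagnostic_model import _delong_components


def two_group_scores(rng, n0=40, n1=60, shift=1.0):
    y = np.r_[np.zeros(n0, bool), np.ones(n1, bool)]
    s = np.r_[rng.standard_normal(n0), rng.standard_normal(n1) + shift]
    return s, y


class TestRocAnalysis:
    def test_perfect_separation(self):
        y = np.r_[np.zeros(10, bool), np.ones(10, bool)]
        s = np.r_[np.zeros(10), np.ones(10)]
        r = roc_analysis(s, y, orientation="higher")
        assert r.auc == 1.0
        assert r.sensitivity == 100.0 and r.specificity == 100.0
        assert 0.0 < r.cutoff < 1.0

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(0)
        y = rng.random(4000) < 0.5
        r = roc_analysis(rng.standard_normal(4000), y)
        assert r.auc == pytest.approx(0.5, abs=0.03)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_auc_equals_normalized_mann_whitney_u(self, seed):
        """Oracle identity: empirical AUC = U / (n1·n0), ties included."""
        rng = np.random.default_rng(seed)
        s, y = two_group_scores(rng)
        s = np.round(s, 1)  # induce ties
        r = roc_analysis(s, y, orientation="higher")
        u = mannwhitneyu(s[y], s[~y]).statistic
        assert r.auc == pytest.approx(u / (y.sum() * (~y).sum()), abs=1e-12)
        assert r.auc == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    @pytest.mark.parametrize("seed", [4, 5])
    def test_youden_cutoff_matches_brute_force_scan(self, seed):
        """The reported cutoff reproduces an exhaustive midpoint scan (n ≤ 50)."""
        rng = np.random.default_rng(seed)
        s, y = two_group_scores(rng, n0=20, n1=25)
        r = roc_analysis(s, y, orientation="higher")
        best = (-1.0, None)
        uniq = np.sort(np.unique(s))
        for c in (uniq[:-1] + uniq[1:]) / 2:
            j = (s[y] >= c).mean() + (s[~y] < c).mean() - 1
            if j > best[0] + 1e-12:
                best = (j, c)
        assert r.sensitivity / 100 + r.specificity / 100 - 1 == pytest.approx(best[0])

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(6)
        s, y = two_group_scores(rng)
        a = roc_analysis(s, y, orientation="higher").auc
        assert roc_analysis(np.exp(s), y, orientation="higher").auc == pytest.approx(a)
        assert roc_analysis(s ** 3, y, orientation="higher").auc == pytest.approx(a)

    def test_lower_orientation_maps_cutoff_back_to_original_scale(self):
        """Markers lower in malignancy: cutoff between group means, ≤ ⇒ malignant."""
        rng = np.random.default_rng(7)
        ben = rng.normal(1.17, 0.34, 73)
        mal = rng.normal(0.73, 0.18, 105)
        s = np.r_[ben, mal]
        y = np.r_[np.zeros(73, bool), np.ones(105, bool)]
        r = roc_analysis(s, y, orientation="lower")
        assert r.auc > 0.5
        assert 0.73 < r.cutoff < 1.17
        # operating point consistent with the ≤-rule on the original scale
        assert r.sensitivity == pytest.approx((mal <= r.cutoff).mean() * 100)
        assert r.specificity == pytest.approx((ben > r.cutoff).mean() * 100)

    def test_one_class_input_rejected(self):
        with pytest.raises(ValueError):
            roc_analysis(np.arange(5.0), np.ones(5, bool))


class TestDelong:
    def test_identical_scores_no_difference(self):
        rng = np.random.default_rng(8)
        s, y = two_group_scores(rng)
        z, p = delong_test(s, s, y, "higher", "higher")
        assert z == 0.0 and p == 1.0

    def test_informative_vs_noise_detected(self):
        rng = np.random.default_rng(9)
        y = np.r_[np.zeros(250, bool), np.ones(250, bool)]
        info = rng.standard_normal(500) + y * 1.2
        noise = rng.standard_normal(500)
        _, p = delong_test(info, noise, y, "higher", "higher")
        assert p < 0.01

    def test_near_identical_scores_not_significant(self):
        rng = np.random.default_rng(10)
        s, y = two_group_scores(rng)
        s2 = s + rng.normal(0, 0.01, s.size)
        _, p = delong_test(s, s2, y, "higher", "higher")
        assert p > 0.05

    def test_agrees_with_paired_bootstrap_oracle(self):
        """DeLong p within 0.02 of a 10⁴-replicate paired-bootstrap p."""
        rng = np.random.default_rng(0)
        n = 60
        y = np.r_[np.zeros(30, bool), np.ones(30, bool)]
        a = rng.standard_normal(n) + y * 0.8
        b = a + rng.normal(0, 0.7, n)
        _, p = delong_test(a, b, y, "higher", "higher")
        rngb = np.random.default_rng(1)
        diffs = []
        for _ in range(10_000):
            idx = rngb.integers(0, n, n)
            yy = y[idx]
            if yy.all() or not yy.any():
                continue
            diffs.append(_delong_components(a[idx], yy)[0]
                         - _delong_components(b[idx], yy)[0])
        diffs = np.asarray(diffs)
        p_boot = 2 * min((diffs <= 0).mean(), (diffs >= 0).mean())
        assert p == pytest.approx(p_boot, abs=0.02)


def cohort_frame(rng, nb=73, nm=105):
    df = pd.DataFrame({
        "D": np.r_[rng.normal(1.17, 0.34, nb), rng.normal(0.73, 0.18, nm)],
        "beta": np.r_[rng.normal(0.86, 0.06, nb), rng.normal(0.77, 0.06, nm)],
        "mu": np.r_[rng.normal(3.06, 0.63, nb), rng.normal(3.39, 0.42, nm)],
    })
    y = np.r_[np.zeros(nb, bool), np.ones(nm, bool)]
    return df, y


class TestLogisticSelection:
    def test_pure_noise_feature_dropped(self):
        rng = np.random.default_rng(11)
        df = pd.DataFrame({"x": rng.standard_normal(400)})
        y = rng.random(400) < 0.5
        m = fit_logistic_with_selection(df, y, features=["x"])
        assert m.retained == []
        assert m.coef == {}
        assert np.allclose(m.fitted_probabilities, m.fitted_probabilities[0])

    def test_selection_frequencies_over_replicates(self):
        """D survives essentially always; µ is excluded appreciably often."""
        keep_d = drop_mu = 0
        n_rep = 200
        for s in range(n_rep):
            rng = np.random.default_rng(1000 + s)
            df, y = cohort_frame(rng)
            m = fit_logistic_with_selection(df, y)
            keep_d += "D" in m.retained
            drop_mu += "mu" not in m.retained
        assert keep_d / n_rep > 0.95
        assert drop_mu / n_rep > 0.10

    def test_collinear_duplicate_features_fall_back_to_penalized(self):
        rng = np.random.default_rng(12)
        df, y = cohort_frame(rng)
        df["D2"] = df["D"]
        m = fit_logistic_with_selection(df, y, features=["D", "D2"], alpha=1.0)
        assert m.penalized
        assert np.all((m.fitted_probabilities > 0) & (m.fitted_probabilities < 1))

    def test_perfect_separation_flagged_and_fitted(self):
        df = pd.DataFrame({"x": np.r_[np.zeros(20), np.ones(20)]})
        y = np.r_[np.zeros(20, bool), np.ones(20, bool)]
        m = fit_logistic_with_selection(df, y, features=["x"], alpha=1.0)
        assert m.penalized
        assert m.coef["x"] > 0


class TestCombinedRoc:
    def test_single_feature_model_matches_marker_auc(self):
        """The logistic transform is monotone, so AUCs coincide."""
        rng = np.random.default_rng(13)
        df, y = cohort_frame(rng)
        m = fit_logistic_with_selection(df, y, features=["D"], alpha=1.0)
        marker = roc_analysis(df["D"], y, orientation="lower")
        assert combined_roc(m, df, y).auc == pytest.approx(marker.auc, abs=1e-12)

    def test_constant_second_feature_changes_nothing(self):
        rng = np.random.default_rng(14)
        df, y = cohort_frame(rng)
        df["const"] = 1.0
        m1 = fit_logistic_with_selection(df, y, features=["D"], alpha=1.0)
        m2 = fit_logistic_with_selection(df, y, features=["D", "const"], alpha=1.0)
        assert combined_roc(m2, df, y).auc == pytest.approx(
            combined_roc(m1, df, y).auc, abs=1e-9)

    def test_independent_signal_improves_auc(self):
        rng = np.random.default_rng(15)
        n = 1000
        y = np.r_[np.zeros(n, bool), np.ones(n, bool)]
        df = pd.DataFrame({
            "a": rng.standard_normal(2 * n) + 0.8 * y,
            "b": rng.standard_normal(2 * n) + 0.8 * y,
        })
        m = fit_logistic_with_selection(df, y, features=["a", "b"], alpha=1.0)
        best_single = max(roc_analysis(df["a"], y).auc, roc_analysis(df["b"], y).auc)
        assert combined_roc(m, df, y).auc >= best_single - 0.01


class TestHosmerLemeshow:
    def test_type_one_error_near_alpha_under_calibration_null(self):
        """Refit-then-test on well-specified data rejects at ≈ 5%."""
        rej = 0
        n_rep, n = 300, 1500
        for s in range(n_rep):
            rng = np.random.default_rng(5000 + s)
            x = rng.standard_normal(n)
            pr = 1 / (1 + np.exp(0.3 - 1.2 * x))
            yy = rng.random(n) < pr
            m = fit_logistic_with_selection(pd.DataFrame({"x": x}), yy,
                                            features=["x"], alpha=1.0)
            _, p = hosmer_lemeshow(m.fitted_probabilities, yy)
            rej += p < 0.05
        assert 0.02 <= rej / n_rep <= 0.09

    def test_miscalibrated_probabilities_rejected(self):
        rng = np.random.default_rng(16)
        pr = rng.uniform(0.05, 0.95, 4000)
        yy = rng.random(4000) < pr
        _, p = hosmer_lemeshow(pr ** 2, yy)
        assert p < 0.01

    def test_minimal_three_bins_runs(self):
        rng = np.random.default_rng(17)
        pr = rng.uniform(0.2, 0.8, 200)
        yy = rng.random(200) < pr
        chi2, p = hosmer_lemeshow(pr, yy, g=3)
        assert chi2 >= 0 and 0 <= p <= 1

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            hosmer_lemeshow([0.2, 0.4, 0.8], [0, 1, 1], g=2)


class TestBootstrapCalibration:
    def test_well_specified_model_calibrates(self):
        rng = np.random.default_rng(18)
        n = 5000
        x = rng.standard_normal(n)
        pr = 1 / (1 + np.exp(-(-0.4 + 1.1 * x)))
        y = rng.random(n) < pr
        df = pd.DataFrame({"x": x})
        m = fit_logistic_with_selection(df, y, features=["x"], alpha=1.0)
        curve = bootstrap_calibration(m, df, y, n_boot=200, seed=0)
        assert np.max(np.abs(curve["observed_corrected"] - curve["predicted"])) < 0.05

    def test_deterministic_given_seed_and_minimum_b(self):
        rng = np.random.default_rng(19)
        df, y = cohort_frame(rng)
        m = fit_logistic_with_selection(df, y)
        c1 = bootstrap_calibration(m, df, y, n_boot=100, seed=5)
        c2 = bootstrap_calibration(m, df, y, n_boot=100, seed=5)
        pd.testing.assert_frame_equal(c1, c2)
        with pytest.raises(ValueError):
            bootstrap_calibration(m, df, y, n_boot=50)


class TestDecisionCurve:
    def test_perfect_classifier_net_benefit_is_prevalence(self):
        y = np.r_[np.zeros(60, bool), np.ones(40, bool)]
        probs = y.astype(float)
        curve = decision_curve(probs, y, thresholds=np.linspace(0.05, 0.95, 19))
        np.testing.assert_allclose(curve.net_benefit, 0.4, atol=1e-12)

    def test_treat_none_is_zero_and_treat_all_crosses_zero_at_prevalence(self):
        rng = np.random.default_rng(20)
        y = np.r_[np.zeros(60, bool), np.ones(40, bool)]
        curve = decision_curve(rng.random(100), y, thresholds=np.array([0.4]))
        assert np.all(curve.treat_none == 0)
        assert curve.treat_all[0] == pytest.approx(0.0, abs=1e-12)

    def test_thresholds_outside_open_interval_rejected(self):
        y = np.r_[np.zeros(5, bool), np.ones(5, bool)]
        with pytest.raises(ValueError):
            decision_curve(np.linspace(0, 1, 10), y, thresholds=np.array([0.0, 0.5]))


class TestNomogram:
    def test_points_reproduce_model_probability(self):
        rng = np.random.default_rng(21)
        df, y = cohort_frame(rng)
        m = fit_logistic_with_selection(df, y, features=["D", "beta"], alpha=1.0)
        nomo = build_nomogram(m, df)
        total = nomo.total_points(df)
        np.testing.assert_allclose(nomo.probability(total),
                                   m.predict_proba(df), atol=1e-10)

    def test_largest_span_feature_reaches_100_points(self):
        rng = np.random.default_rng(22)
        df, y = cohort_frame(rng)
        m = fit_logistic_with_selection(df, y, features=["D", "beta"], alpha=1.0)
        nomo = build_nomogram(m, df)
        maxima = {f: max(float(nomo.feature_points(f, nomo.value_range[f][0])),
                         float(nomo.feature_points(f, nomo.value_range[f][1])))
                  for f in nomo.coef}
        assert max(maxima.values()) == pytest.approx(100.0)
        # per-feature maps are non-negative and monotone in risk
        for f in nomo.coef:
            lo, hi = nomo.value_range[f]
            pts = nomo.feature_points(f, np.linspace(lo, hi, 20))
            assert pts.min() >= -1e-9
            diffs = np.diff(pts)
            assert np.all(diffs >= -1e-12) or np.all(diffs <= 1e-12)

    def test_intercept_only_model_rejected(self):
        rng = np.random.default_rng(23)
        df = pd.DataFrame({"x": rng.standard_normal(200)})
        y = rng.random(200) < 0.5
        m = fit_logistic_with_selection(df, y, features=["x"])
        with pytest.raises(ValueError):
            build_nomogram(m, df)


def test_binormal_auc_converges_to_closed_form():
    """Empirical AUC → Φ(Δµ/√(σ₁²+σ₂²)) on Gaussian two-group data."""
    rng = np.random.default_rng(24)
    n = 40_000
    ben = rng.normal(1.17, 0.34, n)
    mal = rng.normal(0.73, 0.18, n)
    y = np.r_[np.zeros(n, bool), np.ones(n, bool)]
    r = roc_analysis(np.r_[ben, mal], y, orientation="lower")
    expected = norm.cdf((1.17 - 0.73) / np.hypot(0.34, 0.18))
    assert r.auc == pytest.approx(expected, abs=0.005)
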