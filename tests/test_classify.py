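"""Logistic modelling, ROC/DeLong, bootstrap, calibration, decision curves."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from rsifit import (
    TwoByTwoTable,
    bootstrap_validate,
    calibration_curve,
    decision_curve,
    delong_test,
    empirical_auc,
    logistic_fit,
    multivariate_fit,
    odds_ratio_2x2,
    roc_analysis,
    univariate_screen,
)
from rsifit.exceptions import (
    CollinearityError,
    InvalidInputError,
    SeparationError,
)
from rsifit.stats import mann_whitney_u


def sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


class TestLogisticFit:
    def test_binary_predictor_reproduces_2x2_odds_ratio(
        self, study_scores_labels
    ):
        scores, labels = study_scores_labels
        m = logistic_fit(scores[:, None], labels, feature_names=["smoking"])
        closed = odds_ratio_2x2(TwoByTwoTable(21, 9, 21, 46))
        assert m.odds_ratios_[0] == pytest.approx(5.111, abs=5e-4)
        assert m.odds_ratios_[0] == pytest.approx(
            closed.odds_ratio, rel=1e-6
        )
        np.testing.assert_allclose(
            m.or_ci_[0], [closed.ci_low, closed.ci_high], rtol=1e-6
        )

    def test_balanced_independent_table_zero_coefficient(self):
        x = np.r_[np.ones(10), np.zeros(10), np.ones(10), np.zeros(10)]
        y = np.r_[np.ones(20), np.zeros(20)]
        m = logistic_fit(x[:, None], y)
        assert m.coef_[0] == pytest.approx(0.0, abs=1e-10)

    def test_six_row_fit_matches_likelihood_grid_oracle(self):
        x = np.array([-1.2, -0.5, 0.1, 0.4, 1.1, 1.8])
        y = np.array([0, 0, 1, 0, 1, 1])
        m = logistic_fit(x[:, None], y)

        def negll(b0, b1):
            p = sigmoid(b0 + b1 * x)
            return -(y * np.log(p) + (1 - y) * np.log(1 - p)).sum()

        # dense grid over (intercept, slope) around a generous window
        b0s = np.linspace(-3, 3, 601)
        b1s = np.linspace(-1, 6, 701)
        grid = np.array([[negll(a, b) for b in b1s] for a in b0s])
        i, j = np.unravel_index(grid.argmin(), grid.shape)
        assert m.intercept_ == pytest.approx(b0s[i], abs=2e-2)
        assert m.coef_[0] == pytest.approx(b1s[j], abs=2e-2)

    def test_matches_statsmodels_on_continuous_data(self, rng):
        import statsmodels.api as sm

        x = rng.normal(size=(200, 2))
        y = (rng.random(200) < sigmoid(0.3 + x @ [0.8, -1.1])).astype(int)
        m = logistic_fit(x, y, feature_names=["a", "b"])
        ref = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        np.testing.assert_allclose(
            [m.intercept_, *m.coef_], ref.params, rtol=1e-6
        )
        np.testing.assert_allclose(m.se_, ref.bse, rtol=1e-5)

    def test_perfect_separation_names_predictor(self):
        x = np.column_stack([np.r_[np.zeros(10), np.ones(10)],
                             np.random.default_rng(0).normal(size=20)])
        y = np.r_[np.zeros(10), np.ones(10)]
        with pytest.raises(SeparationError) as exc:
            logistic_fit(x, y, feature_names=["sep", "noise"])
        assert exc.value.predictor == "sep"

    def test_collinear_duplicate_rejected(self, rng):
        x = rng.normal(size=50)
        X = np.column_stack([x, 2 * x])
        y = (rng.random(50) < sigmoid(x)).astype(int)
        with pytest.raises(CollinearityError):
            logistic_fit(X, y, feature_names=["x", "x2"])

    def test_constant_column_rejected(self, rng):
        X = np.column_stack([np.ones(40), rng.normal(size=40)])
        y = np.r_[np.ones(20), np.zeros(20)]
        with pytest.raises(CollinearityError, match="constant"):
            logistic_fit(X, y, feature_names=["const", "x"])


class TestScreenAndMultivariate:
    def test_smoking_screen_passes_on_study_counts(self, study_scores_labels):
        scores, labels = study_scores_labels
        cohort = pd.DataFrame({"smoking": scores})
        table = univariate_screen(cohort, ["smoking"], labels)
        assert bool(table.loc[0, "passed"])
        assert table.loc[0, "p_value"] < 0.001

    def test_empty_candidate_list_empty_table(self):
        cohort = pd.DataFrame({"x": [1.0, 2.0]})
        assert len(univariate_screen(cohort, [], np.array([0, 1]))) == 0

    def test_null_candidate_excluded_at_nominal_rate(self):
        # a pure-noise candidate's p-value is uniform: it should fail the
        # alpha=0.05 screen in ~95% of replicates
        rng = np.random.default_rng(99)
        n, reps, excluded = 100, 1000, 0
        y = np.r_[np.ones(n // 2, int), np.zeros(n // 2, int)]
        for _ in range(reps):
            cohort = pd.DataFrame({"noise": rng.normal(size=n)})
            t = univariate_screen(cohort, ["noise"], y)
            excluded += not bool(t.loc[0, "passed"])
        assert 0.93 * reps <= excluded <= 0.97 * reps

    def test_single_candidate_equals_univariate(self, study_scores_labels):
        scores, labels = study_scores_labels
        cohort = pd.DataFrame({"smoking": scores.astype(float)})
        uni = univariate_screen(cohort, ["smoking"], labels)
        multi = multivariate_fit(cohort, ["smoking"], labels)
        assert multi.odds_ratios_[0] == pytest.approx(
            uni.loc[0, "odds_ratio"], rel=1e-9
        )

    def test_backward_elimination_recovers_true_predictors(self):
        # only f1 and smoking carry signal; backward elimination should
        # retain exactly that pair in the vast majority of replicates
        retained_exact = 0
        reps, n = 100, 2000
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            f1 = rng.normal(0, 1, n)
            smoking = (rng.random(n) < 0.4).astype(float)
            junk = rng.normal(size=n)
            y = (rng.random(n) < sigmoid(-0.5 + 0.9 * f1 + 1.2 * smoking))
            cohort = pd.DataFrame(
                {"f1": f1, "smoking": smoking, "junk": junk}
            )
            m = multivariate_fit(
                cohort, ["f1", "smoking", "junk"], y.astype(int),
                elimination="backward",
            )
            retained_exact += set(m.feature_names_) == {"f1", "smoking"}
        assert retained_exact >= 90

    def test_collinear_entry_raises(self, rng):
        x = rng.normal(size=100)
        y = (rng.random(100) < sigmoid(x)).astype(int)
        cohort = pd.DataFrame({"x": x, "x_dup": x})
        with pytest.raises(CollinearityError):
            multivariate_fit(cohort, ["x", "x_dup"], y)


class TestROC:
    def test_smoking_operating_point(self, study_scores_labels):
        scores, labels = study_scores_labels
        r = roc_analysis(scores, labels)
        assert r.auc == pytest.approx(0.693, abs=5e-4)
        assert r.sensitivity == pytest.approx(0.7000, abs=5e-5)
        assert r.specificity == pytest.approx(0.6866, abs=5e-5)

    def test_binary_score_auc_identity(self, study_scores_labels):
        scores, labels = study_scores_labels
        r = roc_analysis(scores, labels)
        assert r.auc == pytest.approx(
            (r.sensitivity + r.specificity) / 2, abs=1e-12
        )

    def test_perfect_and_tied_scores(self):
        y = np.r_[np.ones(5, int), np.zeros(5, int)]
        assert roc_analysis(np.r_[np.ones(5), np.zeros(5)], y).auc == 1.0
        assert roc_analysis(np.ones(10), y).auc == 0.5

    def test_auc_matches_sklearn_and_mann_whitney(self, rng):
        scores = rng.normal(size=80) + np.r_[np.ones(40), np.zeros(40)]
        labels = np.r_[np.ones(40, int), np.zeros(40, int)]
        auc = empirical_auc(scores, labels)
        assert auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)
        u = mann_whitney_u(scores[labels == 1], scores[labels == 0])
        assert auc == pytest.approx(u / (40 * 40), abs=1e-12)

    def test_cutoff_midway_between_observed_scores(self):
        scores = np.array([0.1, 0.2, 0.6, 0.8])
        labels = np.array([0, 0, 1, 1])
        r = roc_analysis(scores, labels)
        assert r.cutoff == pytest.approx(0.4)

    def test_youden_tie_broken_toward_sensitivity(self):
        # two cutoffs attain J = 0: choose the all-positive one (sens 1)
        scores = np.array([1.0, 1.0, 2.0, 2.0])
        labels = np.array([1, 0, 1, 0])
        r = roc_analysis(scores, labels)
        assert r.sensitivity == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(InvalidInputError):
            roc_analysis([0.1, 0.9], [1, 1])


class TestDeLong:
    def test_identical_scores_null(self, rng):
        s = rng.normal(size=60)
        y = (rng.random(60) < 0.5).astype(int)
        y[:3], y[-3:] = 1, 0
        d = delong_test(s, s, y)
        assert d.z == 0.0 and d.p_value == 1.0 and d.delta == 0.0

    def test_monotone_transform_invariance(self, rng):
        s = rng.normal(size=50)
        y = np.r_[np.ones(25, int), np.zeros(25, int)]
        d = delong_test(s, np.exp(2 * s) + 5, y)
        assert d.z == 0.0

    def test_eight_case_variance_against_placement_oracle(self):
        sa = np.array([0.9, 0.8, 0.7, 0.6, 0.55, 0.4, 0.3, 0.2])
        sb = np.array([0.7, 0.9, 0.3, 0.8, 0.25, 0.6, 0.5, 0.1])
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0])

        def placements(s):
            pos, neg = s[y == 1], s[y == 0]
            v10 = np.array(
                [np.mean((p > neg) + 0.5 * (p == neg)) for p in pos]
            )
            v01 = np.array(
                [np.mean((pos > n) + 0.5 * (pos == n)) for n in neg]
            )
            return v10, v01

        v10a, v01a = placements(sa)
        v10b, v01b = placements(sb)
        auc_a, auc_b = v10a.mean(), v10b.mean()
        s10 = np.cov(np.vstack([v10a, v10b]))
        s01 = np.cov(np.vstack([v01a, v01b]))
        var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / 4 + (
            s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
        ) / 4
        z_oracle = (auc_a - auc_b) / np.sqrt(var)
        d = delong_test(sa, sb, y)
        assert d.delta == pytest.approx(auc_a - auc_b, abs=1e-12)
        assert d.z == pytest.approx(z_oracle, rel=1e-10)

    def test_unpaired_lengths_rejected(self):
        with pytest.raises(InvalidInputError):
            delong_test([0.1, 0.2], [0.3], [1, 0])


class TestBootstrapValidation:
    @staticmethod
    def _cohort(n=97, seed=0):
        rng = np.random.default_rng(seed)
        x1 = rng.normal(size=n)
        x2 = (rng.random(n) < 0.4).astype(float)
        y = (rng.random(n) < sigmoid(-0.4 + 0.9 * x1 + 0.6 * x2)).astype(int)
        if y.sum() < 2 or y.sum() > n - 2:  # keep both classes populated
            y[:2], y[-2:] = 1, 0
        return pd.DataFrame({"x1": x1, "x2": x2}), y

    def test_identity_resample_gives_zero_optimism(self, monkeypatch):
        cohort, y = self._cohort()

        class IdentityRng:
            def choice(self, idx, size, replace):
                return idx

        monkeypatch.setattr(
            "rsifit.classify.np.random.default_rng",
            lambda seed=None: IdentityRng(),
        )
        rep = bootstrap_validate(cohort, ["x1", "x2"], y, B=1, seed=0)
        assert rep.optimism == 0.0
        assert rep.corrected_auc == rep.apparent_auc

    def test_deterministic_given_seed(self):
        cohort, y = self._cohort()
        a = bootstrap_validate(cohort, ["x1", "x2"], y, B=50, seed=3)
        b = bootstrap_validate(cohort, ["x1", "x2"], y, B=50, seed=3)
        assert a == b

    def test_optimism_usually_nonnegative(self):
        # apparent performance should rarely beat the corrected estimate
        wins = 0
        for seed in range(100):
            cohort, y = self._cohort(seed=seed)
            rep = bootstrap_validate(cohort, ["x1", "x2"], y, B=200,
                                     seed=seed)
            wins += rep.corrected_auc <= rep.apparent_auc
        assert wins >= 95

    def test_interval_brackets_mean(self):
        cohort, y = self._cohort(seed=5)
        rep = bootstrap_validate(cohort, ["x1", "x2"], y, B=200, seed=1)
        assert rep.ci_low <= rep.bootstrap_mean_auc <= rep.ci_high


class TestCalibration:
    def test_self_consistent_predictions_slope_one(self):
        rng = np.random.default_rng(21)
        p = rng.uniform(0.05, 0.95, 10_000)
        y = (rng.random(10_000) < p).astype(int)
        cal = calibration_curve(p, y)
        assert cal.slope == pytest.approx(1.0, abs=0.05)
        assert cal.intercept == pytest.approx(0.0, abs=0.05)
        assert len(cal.curve) == 10

    def test_constant_prediction_single_bin(self):
        p = np.full(100, 0.5)
        y = np.r_[np.ones(50, int), np.zeros(50, int)]
        with pytest.warns(UserWarning):
            cal = calibration_curve(p, y)
        assert cal.n_bins == 1
        assert cal.curve["observed_frequency"].iloc[0] == 0.5
        assert np.isnan(cal.slope)

    def test_anticalibrated_negative_slope(self):
        rng = np.random.default_rng(22)
        truth = rng.uniform(0.05, 0.95, 10_000)
        y = (rng.random(10_000) < truth).astype(int)
        cal = calibration_curve(1 - truth, y)
        assert cal.slope < 0

    def test_out_of_range_predictions_rejected(self):
        with pytest.raises(InvalidInputError):
            calibration_curve([0.0, 0.5], [0, 1])


class TestDecisionCurve:
    def test_treat_none_zero_and_treat_all_closed_form(self):
        rng = np.random.default_rng(30)
        p = rng.uniform(0.01, 0.99, 500)
        y = (rng.random(500) < p).astype(int)
        dc = decision_curve(p, y, thresholds=[0.25, 0.5, 0.75])
        assert (dc.table["nb_none"] == 0).all()
        prev = y.mean()
        at_half = dc.table.set_index("threshold").loc[0.5, "nb_all"]
        assert at_half == pytest.approx(2 * prev - 1, abs=1e-12)

    def test_perfect_predictor_net_benefit_is_prevalence(self):
        y = np.r_[np.ones(20, int), np.zeros(80, int)]
        p = np.r_[np.full(20, 0.95), np.full(80, 0.02)]
        dc = decision_curve(p, y, thresholds=[0.1, 0.5, 0.9])
        np.testing.assert_allclose(dc.table["nb_model"], 0.2, atol=1e-12)

    def test_net_benefit_bounded_by_prevalence(self):
        rng = np.random.default_rng(31)
        p = rng.uniform(0.01, 0.99, 300)
        y = (rng.random(300) < p).astype(int)
        dc = decision_curve(p, y)
        assert (dc.table["nb_model"] <= y.mean() + 1e-12).all()

    def test_invalid_threshold_rejected(self):
        with pytest.raises(InvalidInputError):
            decision_curve([0.5], [1], thresholds=[1.0])
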