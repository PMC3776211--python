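"""Logistic diagnostic, ROC, likelihood ratios and Bayesian updates."""
import itertools
import math

import numpy as np
import pandas as pd
import pytest

from rapatest.diagnostic import (ConfusionTable, DiagnosticModel,
                                 PrevalenceModel, SeparationWarning,
                                 likelihood_ratio_positive, lr_at_score,
                                 operating_point, posttest_probability,
                                 pretest_probability, roc_analysis,
                                 validate_frozen)


def simulate_logistic(beta0, beta1, n, seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(0, 1, n)
    p = 1 / (1 + np.exp(-(beta0 + beta1 * x)))
    y = rng.random(n) < p
    return pd.DataFrame({"x": x}), y.astype(float)


class TestLogistic:
    def test_symmetric_data_zero_intercept(self):
        rng = np.random.default_rng(0)
        x = np.repeat([-1.0, 1.0], 500)
        y = (x > 0).astype(float)
        flip = rng.random(1000) < 0.10
        y[flip] = 1 - y[flip]
        res = DiagnosticModel(pd.DataFrame({"x": x}), y,
                              feature_names=("x",)).fit()
        assert abs(res.params["intercept"]) < 3 * res.bse["intercept"]

    def test_parameter_recovery_within_3se(self):
        X, y = simulate_logistic(-1.0, 2.0, 5000, seed=3)
        res = DiagnosticModel(X, y, feature_names=("x",)).fit()
        assert abs(res.params["intercept"] - (-1.0)) < 3 * res.bse["intercept"]
        assert abs(res.params["x"] - 2.0) < 3 * res.bse["x"]

    def test_matches_statsmodels(self):
        """Independent cross-check of the IRLS fit against statsmodels."""
        import statsmodels.api as sm

        X, y = simulate_logistic(-0.5, 1.2, 400, seed=8)
        res = DiagnosticModel(X, y, feature_names=("x",)).fit()
        ref = sm.Logit(y, sm.add_constant(X["x"])).fit(disp=0)
        assert res.params["intercept"] == pytest.approx(ref.params["const"],
                                                        abs=1e-5)
        assert res.params["x"] == pytest.approx(ref.params["x"], abs=1e-5)
        assert res.bse["x"] == pytest.approx(ref.bse["x"], rel=1e-3)

    def test_separation_triggers_ridge_fallback(self):
        x = np.concatenate([np.full(10, -2.0), np.full(10, 2.0)])
        y = (x > 0).astype(float)
        with pytest.warns(SeparationWarning):
            res = DiagnosticModel(pd.DataFrame({"x": x}), y,
                                  feature_names=("x",)).fit()
        assert res.ridge_fallback
        assert np.all(np.isfinite(res.params))

    def test_single_class_rejected(self):
        X = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0]})
        with pytest.raises(ValueError):
            DiagnosticModel(X, [1, 1, 1, 1], feature_names=("x",))

    def test_apoe_covariate_never_hurts_likelihood(self):
        rng = np.random.default_rng(5)
        n = 300
        df = pd.DataFrame({"x": rng.normal(0, 1, n),
                           "apoe4": rng.integers(0, 2, n).astype(float)})
        y = (rng.random(n) < 1 / (1 + np.exp(-df["x"]))).astype(float)
        base = DiagnosticModel(df, y, feature_names=("x",)).fit()
        nested = DiagnosticModel(df, y, feature_names=("x", "apoe4")).fit()
        assert nested.log_likelihood >= base.log_likelihood - 1e-8


class TestPredict:
    @staticmethod
    def fitted():
        X, y = simulate_logistic(0.0, 1.0, 200, seed=1)
        return DiagnosticModel(X, y, feature_names=("x",)).fit()

    def test_logit_identities(self):
        res = self.fitted()
        # force known coefficients to test the inverse-logit mapping
        res.params[:] = [0.0, 1.0]
        assert res.predict(pd.DataFrame({"x": [0.0]}))[0] == pytest.approx(0.5)
        assert res.predict(pd.DataFrame({"x": [math.log(3)]}))[0] == \
            pytest.approx(0.75)

    def test_batch_equals_per_subject(self):
        res = self.fitted()
        X = pd.DataFrame({"x": np.linspace(-2, 2, 9)})
        batch = res.predict(X)
        singles = [res.predict(X.iloc[[i]])[0] for i in range(len(X))]
        np.testing.assert_allclose(batch, singles, rtol=1e-12)

    def test_missing_feature_rejected(self):
        res = self.fitted()
        with pytest.raises(KeyError):
            res.predict(pd.DataFrame({"y": [1.0]}))


def brute_force_auc(scores, labels):
    """Exhaustive pair-counting oracle: P(random positive > random negative)."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p, n in itertools.product(pos, neg))
    return wins / (len(pos) * len(neg))


class TestROC:
    def test_perfect_separation(self):
        roc = roc_analysis([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0], n_boot=50)
        assert roc.auc == 1.0

    def test_all_ties(self):
        roc = roc_analysis([0.5] * 8, [1, 1, 1, 1, 0, 0, 0, 0], n_boot=50)
        assert roc.auc == 0.5

    def test_six_score_pair_oracle(self):
        scores = [0.1, 0.4, 0.35, 0.8, 0.65, 0.9]
        labels = [0, 0, 1, 1, 0, 1]
        roc = roc_analysis(scores, labels, n_boot=50)
        assert roc.auc == pytest.approx(brute_force_auc(scores, labels))

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_oracle_small_n(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 21))
        labels = np.r_[np.ones(2), np.zeros(2),
                       rng.integers(0, 2, n - 4)].astype(float)
        scores = np.round(rng.random(n), 2)  # rounded to force some ties
        roc = roc_analysis(scores, labels, n_boot=10, seed=seed)
        assert roc.auc == pytest.approx(brute_force_auc(scores, labels))

    def test_bootstrap_ci_reproducible(self):
        s = np.linspace(0, 1, 30)
        y = (s + np.random.default_rng(0).normal(0, 0.3, 30) > 0.5).astype(float)
        a = roc_analysis(s, y, n_boot=200, seed=7)
        b = roc_analysis(s, y, n_boot=200, seed=7)
        assert a.auc_ci == b.auc_ci
        assert a.auc_ci[0] <= a.auc <= a.auc_ci[1]

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_analysis([0.1, 0.9], [1, 1], n_boot=10)


class TestOperatingPoint:
    def test_perfect_split_haldane_correction(self):
        roc = roc_analysis([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0], n_boot=10)
        table = operating_point(roc, 0.5)
        assert table.sensitivity == 1.0 and table.specificity == 1.0
        or_, ci, corrected = table.odds_ratio()
        assert corrected and math.isfinite(or_)

    def test_contingency_arithmetic(self):
        table = ConfusionTable(tp=40, fp=9, tn=55, fn=8)
        or_, _, corrected = table.odds_ratio()
        assert not corrected
        assert or_ == pytest.approx((40 * 55) / (9 * 8))  # 30.56

    def test_cutoff_zero_everything_positive(self):
        roc = roc_analysis([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0], n_boot=10)
        table = operating_point(roc, 0.0)
        assert table.specificity == 0.0 and table.sensitivity == 1.0

    def test_strict_cutoff_rule(self):
        roc = roc_analysis([0.5, 0.6], [0, 1], n_boot=10)
        table = operating_point(roc, 0.5)
        assert table.fp == 0  # score == cutoff is negative under '>'


class TestLikelihoodRatio:
    def test_arithmetic(self):
        assert likelihood_ratio_positive(0.9, 0.9) == pytest.approx(9.0)
        assert likelihood_ratio_positive(0.5, 0.5) == pytest.approx(1.0)

    def test_perfect_specificity_infinite(self):
        assert math.isinf(likelihood_ratio_positive(0.8, 1.0))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            likelihood_ratio_positive(1.2, 0.5)

    def test_consistency_with_confusion_counts(self):
        scores = [0.9, 0.7, 0.6, 0.4, 0.3, 0.2]
        labels = [1, 1, 0, 1, 0, 0]
        roc = roc_analysis(scores, labels, n_boot=10)
        table = operating_point(roc, 0.5)
        assert lr_at_score(roc, 0.5) == pytest.approx(
            likelihood_ratio_positive(table.sensitivity, table.specificity))


class TestPretestPosttest:
    def test_prevalence_anchors(self):
        assert pretest_probability(57) == pytest.approx(0.023)
        assert pretest_probability(95) == pytest.approx(0.405)

    def test_prevalence_monotone(self):
        vals = [pretest_probability(a) for a in range(57, 96)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_age_outside_domain_rejected(self):
        with pytest.raises(ValueError):
            pretest_probability(45)

    def test_user_table_replaces_model(self):
        model = PrevalenceModel(table={60: 0.1, 90: 0.3})
        assert model(61) == 0.1 and model(89) == 0.3

    def test_uninformative_lr(self):
        assert posttest_probability(0.3, 1.0) == pytest.approx(0.3)

    def test_odds_arithmetic(self):
        assert posttest_probability(0.2, 4.0) == pytest.approx(0.5)

    def test_inverse_property(self):
        for pre in (0.05, 0.2, 0.5, 0.9):
            for lr in (0.25, 2.0, 17.0):
                back = posttest_probability(posttest_probability(pre, lr), 1 / lr)
                assert back == pytest.approx(pre, abs=1e-12)

    def test_monotone_in_lr_and_pretest(self):
        lrs = [0.5, 1, 2, 4, 8]
        post = [posttest_probability(0.2, lr) for lr in lrs]
        assert post == sorted(post)
        pres = [0.1, 0.2, 0.4, 0.8]
        post = [posttest_probability(p, 3.0) for p in pres]
        assert post == sorted(post)

    def test_degenerate_pretest_returned_unchanged(self):
        with pytest.warns(UserWarning):
            assert posttest_probability(1.0, 5.0) == 1.0


class TestValidateFrozen:
    @staticmethod
    def fit_cohort(seed, n=120):
        X, y = simulate_logistic(-0.5, 1.5, n, seed=seed)
        X.index = [f"c{seed}_{i}" for i in range(n)]
        return X, y

    def test_identical_cohort_sanity(self):
        X, y = self.fit_cohort(1)
        res = DiagnosticModel(X, y, feature_names=("x",),
                              cohort_id="cohort-1").fit()
        report = validate_frozen(res, X, y, cohort_id="cohort-sanity")
        scores = res.predict(X)
        roc = roc_analysis(scores, y, n_boot=10)
        assert report["auc"] == pytest.approx(roc.auc)

    def test_overlap_rejected(self):
        X, y = self.fit_cohort(1)
        res = DiagnosticModel(X, y, feature_names=("x",),
                              cohort_id="cohort-1").fit()
        with pytest.raises(ValueError, match="overlap"):
            validate_frozen(res, X, y, cohort_id="cohort-2",
                            subject_ids=list(X.index))

    def test_empty_cohort_rejected(self):
        X, y = self.fit_cohort(1)
        res = DiagnosticModel(X, y, feature_names=("x",)).fit()
        with pytest.raises(ValueError, match="empty"):
            validate_frozen(res, X.iloc[:0], [], cohort_id="cohort-2")

    def test_exchangeable_split_auc_within_ci(self):
        X, y = simulate_logistic(-0.5, 1.5, 400, seed=4)
        train, vtest = X.iloc[:250], X.iloc[250:]
        res = DiagnosticModel(train, y[:250], feature_names=("x",),
                              cohort_id="cohort-1").fit()
        roc = roc_analysis(res.predict(train), y[:250], n_boot=500, seed=0)
        report = validate_frozen(res, vtest, y[250:], cohort_id="cohort-2")
        assert roc.auc_ci[0] - 0.05 <= report["auc"] <= roc.auc_ci[1] + 0.05
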