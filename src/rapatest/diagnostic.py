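"""The lymphocyte rapamycin-response diagnostic.

A logistic regression on per-subject kinetics (baseline PDT, and the
rapamycin-induced PDT and G1-time lengthening ratios, optionally joined by
ApoE4 carrier status) produces a probability-of-AD risk score.  The score is
evaluated with ROC analysis, sensitivity/specificity at the strict >0.5
cut-off, positive likelihood ratios, and Bayesian pre-to-post-test
probability updates on the odds scale.  A fitted model can be frozen and
applied unchanged to an independent validation cohort.

Organised statsmodels-style: :class:`DiagnosticModel` is built from data,
``fit()`` returns a :class:`DiagnosticResults` carrying coefficients,
standard errors and evaluation methods.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DiagnosticModel", "DiagnosticResults", "ROCCurve", "ConfusionTable",
    "RiskReport", "fit_logistic", "roc_analysis", "operating_point",
    "likelihood_ratio_positive", "pretest_probability", "posttest_probability",
    "validate_frozen", "DEFAULT_FEATURES", "PrevalenceModel",
]

DEFAULT_FEATURES = ("pdt_baseline", "pdt_ratio", "g1_ratio")


# --------------------------------------------------------------------------
# Logistic regression by IRLS with a weak-ridge separation fallback
# --------------------------------------------------------------------------

class SeparationWarning(UserWarning):
    pass


def _irls(X: np.ndarray, y: np.ndarray, lam: float = 0.0,
          tol: float = 1e-8, max_iter: int = 100):
    """Iteratively reweighted least squares for the logistic likelihood.

    ``lam`` is a ridge penalty on all coefficients except the intercept
    (column 0).  Returns (beta, cov, n_iter, converged, diverged) where
    ``diverged`` marks a coefficient norm blowing up (quasi-complete
    separation).
    """
    n, p = X.shape
    beta = np.zeros(p)
    pen = np.full(p, lam)
    pen[0] = 0.0
    ll_old = -np.inf
    diverged = False
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        w = mu * (1 - mu)
        ll = float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu))
                   - 0.5 * np.sum(pen * beta ** 2))
        grad = X.T @ (y - mu) - pen * beta
        H = (X * w[:, None]).T @ X + np.diag(pen)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            diverged = True
            break
        beta = beta + step
        if np.linalg.norm(beta) > 1e3:
            diverged = True
            break
        if abs(ll - ll_old) < tol:
            ll_old = ll
            break
        ll_old = ll
    eta = X @ beta
    mu = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1 - 1e-12)
    # quasi-complete separation: every observation fitted (near-)perfectly,
    # so the MLE sits at infinity even though the likelihood has flattened
    if lam == 0 and np.all(np.abs(y - mu) < 1e-3):
        diverged = True
    w = mu * (1 - mu)
    H = (X * w[:, None]).T @ X + np.diag(pen)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
    return beta, cov, it, not diverged, diverged


@dataclass
class DiagnosticResults:
    """Fitted diagnostic: coefficients, uncertainties, scoring and summary."""

    params: pd.Series                 # intercept + per-feature log-odds
    bse: pd.Series                    # asymptotic standard errors
    feature_names: tuple
    cohort_id: str
    n_obs: int
    n_iter: int
    converged: bool
    ridge_fallback: bool
    log_likelihood: float
    model: "DiagnosticModel" = field(repr=False, default=None)

    def linear_predictor(self, features: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.feature_names if f not in features.columns]
        if missing:
            raise KeyError(f"missing features: {missing}")
        X = np.column_stack(
            [np.ones(len(features))]
            + [np.asarray(features[f], dtype=float) for f in self.feature_names])
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite feature values")
        return X @ self.params.to_numpy()

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        """Probability of AD for each row (inverse logit of the score)."""
        return 1.0 / (1.0 + np.exp(-self.linear_predictor(features)))

    def summary(self) -> str:
        lines = [
            "Lymphocyte rapamycin-response diagnostic (logistic regression)",
            f"  cohort: {self.cohort_id}   n={self.n_obs}   "
            f"iterations={self.n_iter}   converged={self.converged}"
            + ("   [ridge fallback]" if self.ridge_fallback else ""),
            f"  log-likelihood: {self.log_likelihood:.4f}",
            f"  {'term':<14}{'coef':>12}{'std err':>12}",
        ]
        for name in self.params.index:
            lines.append(f"  {name:<14}{self.params[name]:>12.4f}"
                         f"{self.bse[name]:>12.4f}")
        return "\n".join(lines)


class DiagnosticModel:
    """Logistic model of diagnosis (AD=1 vs Control=0) on kinetic features.

    MCI subjects may be *scored* with a fitted model but are never used for
    fitting: pass only AD/Control rows (``from_dataframe`` filters them).
    """

    def __init__(self, features: pd.DataFrame, labels, *,
                 feature_names=DEFAULT_FEATURES, cohort_id: str = "cohort-1"):
        y = np.asarray(labels, dtype=float)
        if set(np.unique(y)) - {0.0, 1.0}:
            raise ValueError("labels must be binary 0/1")
        if len(np.unique(y)) < 2:
            raise ValueError("both classes must be present")
        if y.size < len(feature_names) + 1:
            raise ValueError("need n >= number of features + 1")
        if np.unique(y).size == 2 and (np.sum(y == 0) < 2 or np.sum(y == 1) < 2):
            raise ValueError("need >= 2 subjects per class")
        missing = [f for f in feature_names if f not in features.columns]
        if missing:
            raise KeyError(f"missing features: {missing}")
        X = np.column_stack(
            [np.ones(y.size)]
            + [np.asarray(features[f], dtype=float) for f in feature_names])
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite feature values (cap ratios first)")
        self.exog, self.endog = X, y
        self.feature_names = tuple(feature_names)
        self.cohort_id = cohort_id
        self.subject_ids = (list(features.index) if features.index.is_unique
                            else list(range(len(features))))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, *, feature_names=DEFAULT_FEATURES,
                       diagnosis_col: str = "diagnosis",
                       cohort_id: str = "cohort-1") -> "DiagnosticModel":
        """Build from a per-subject table with a diagnosis column.

        Keeps AD and Control rows only (MCI excluded from fitting).
        """
        sub = df[df[diagnosis_col].isin(["AD", "Control"])]
        y = (sub[diagnosis_col] == "AD").astype(float)
        return cls(sub, y, feature_names=feature_names, cohort_id=cohort_id)

    def fit(self, *, tol: float = 1e-8, max_iter: int = 100,
            ridge_lambda: float = 1e-4) -> DiagnosticResults:
        beta, cov, n_iter, conv, diverged = _irls(
            self.exog, self.endog, 0.0, tol, max_iter)
        fallback = False
        if diverged or not np.all(np.isfinite(beta)):
            warnings.warn(
                "quasi-complete separation detected; refitting with weak "
                f"ridge penalty (lambda={ridge_lambda})", SeparationWarning,
                stacklevel=2)
            beta, cov, n_iter, conv, _ = _irls(
                self.exog, self.endog, ridge_lambda, tol, max_iter)
            fallback = True
        names = ["intercept", *self.feature_names]
        mu = np.clip(1 / (1 + np.exp(-(self.exog @ beta))), 1e-12, 1 - 1e-12)
        ll = float(np.sum(self.endog * np.log(mu)
                          + (1 - self.endog) * np.log(1 - mu)))
        return DiagnosticResults(
            params=pd.Series(beta, index=names),
            bse=pd.Series(np.sqrt(np.diag(cov)), index=names),
            feature_names=self.feature_names, cohort_id=self.cohort_id,
            n_obs=int(self.endog.size), n_iter=n_iter, converged=conv,
            ridge_fallback=fallback, log_likelihood=ll, model=self)


def fit_logistic(features: pd.DataFrame, labels, **kwargs) -> DiagnosticResults:
    """Functional wrapper: ``DiagnosticModel(features, labels).fit()``."""
    fit_kw = {k: kwargs.pop(k) for k in ("tol", "max_iter", "ridge_lambda")
              if k in kwargs}
    return DiagnosticModel(features, labels, **kwargs).fit(**fit_kw)


# --------------------------------------------------------------------------
# ROC / operating points / likelihood ratios
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ROCCurve:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_ci: tuple
    n_pos: int
    n_neg: int
    scores: np.ndarray = field(repr=False, default=None)
    labels: np.ndarray = field(repr=False, default=None)
    seed: int | None = None


@dataclass(frozen=True)
class ConfusionTable:
    tp: int
    fp: int
    tn: int
    fn: int
    haldane_corrected: bool = False

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else math.nan

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else math.nan

    @property
    def accuracy(self) -> float:
        n = self.tp + self.fp + self.tn + self.fn
        return (self.tp + self.tn) / n if n else math.nan

    def odds_ratio(self) -> tuple[float, tuple[float, float], bool]:
        """Diagnostic odds ratio with a Woolf log-scale 95% CI.

        A zero cell triggers the Haldane-Anscombe 0.5 correction (flagged).
        """
        a, b, c, d = self.tp, self.fp, self.tn, self.fn
        corrected = 0 in (a, b, c, d)
        if corrected:
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        or_ = (a * c) / (b * d)
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        lo = math.exp(math.log(or_) - 1.959963984540054 * se)
        hi = math.exp(math.log(or_) + 1.959963984540054 * se)
        return or_, (lo, hi), corrected


def _auc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the Mann-Whitney pair-counting estimator (ties count 1/2)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    # rank-based computation, equivalent to pair counting
    from scipy.stats import rankdata
    ranks = rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: pos.size].sum()
    u = r_pos - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def roc_analysis(scores, labels, n_boot: int = 2000, seed: int = 0) -> ROCCurve:
    """ROC curve with Mann-Whitney AUC and a stratified percentile bootstrap CI."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    n_pos, n_neg = int(np.sum(y == 1)), int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present for ROC analysis")

    thr = np.unique(s)
    # decisions are strict '>': include -inf so the all-positive point appears
    thresholds = np.concatenate([[-np.inf], thr])
    sens = np.array([(s[y == 1] > t).mean() for t in thresholds])
    spec = np.array([(s[y == 0] <= t).mean() for t in thresholds])
    auc = _auc_mann_whitney(s, y)

    rng = np.random.default_rng(seed)
    pos_idx, neg_idx = np.where(y == 1)[0], np.where(y == 0)[0]
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bi = np.concatenate([rng.choice(pos_idx, n_pos, replace=True),
                             rng.choice(neg_idx, n_neg, replace=True)])
        boots[b] = _auc_mann_whitney(s[bi], y[bi])
    ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
    return ROCCurve(thresholds=thresholds, sensitivity=sens, specificity=spec,
                    auc=auc, auc_ci=ci, n_pos=n_pos, n_neg=n_neg,
                    scores=s, labels=y, seed=seed)


def operating_point(roc: ROCCurve, cutoff: float = 0.5) -> ConfusionTable:
    """Confusion table at a cut-off with the strict ``score > cutoff`` rule."""
    if not (0 <= cutoff <= 1):
        raise ValueError("cutoff must be in [0, 1]")
    pred = roc.scores > cutoff
    y = roc.labels.astype(bool)
    return ConfusionTable(tp=int(np.sum(pred & y)), fp=int(np.sum(pred & ~y)),
                          tn=int(np.sum(~pred & ~y)), fn=int(np.sum(~pred & y)))


def likelihood_ratio_positive(sens: float, spec: float) -> float:
    """LR+ = sensitivity / (1 - specificity); perfect specificity gives +inf."""
    if not (0 <= sens <= 1 and 0 <= spec <= 1):
        raise ValueError("sensitivity and specificity must be in [0, 1]")
    if spec == 1.0:
        return math.inf
    return sens / (1.0 - spec)


def lr_at_score(roc: ROCCurve, score: float) -> float:
    """LR+ of the ROC operating point at an individual's score threshold."""
    pred_sens = float((roc.scores[roc.labels == 1] > score).mean())
    pred_spec = float((roc.scores[roc.labels == 0] <= score).mean())
    return likelihood_ratio_positive(pred_sens, pred_spec)


# --------------------------------------------------------------------------
# Pre-/post-test probability (Bayes on the odds scale)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PrevalenceModel:
    """Age-dependent AD prevalence: exponential doubling between two anchors.

    ``p(age) = p_low * 2^((age - age_low)/doubling_years)`` clipped to
    [p_low, p_high], with the doubling time set so that p(age_high)=p_high.
    The default anchors span 2.3% at 57 years to 40.5% at 95 years.  A user
    table (age -> probability) can replace the model entirely.
    """

    p_low: float = 0.023
    p_high: float = 0.405
    age_low: int = 57
    age_high: int = 95
    table: dict | None = None

    @property
    def doubling_years(self) -> float:
        return (self.age_high - self.age_low) / math.log2(self.p_high / self.p_low)

    def __call__(self, age: float) -> float:
        if not (50 <= age <= 100):
            raise ValueError(f"age {age} outside the model domain [50, 100]")
        if self.table is not None:
            key = min(self.table, key=lambda a: abs(a - age))
            return float(self.table[key])
        p = self.p_low * 2.0 ** ((age - self.age_low) / self.doubling_years)
        return float(min(max(p, self.p_low), self.p_high))


def pretest_probability(age: float,
                        prevalence_model: PrevalenceModel | None = None) -> float:
    """Age-based probability of AD before any test result."""
    return (prevalence_model or PrevalenceModel())(age)


def posttest_probability(pretest: float, lr: float) -> float:
    """Update a pre-test probability with a likelihood ratio on the odds scale."""
    if not (0 <= pretest <= 1):
        raise ValueError("pretest probability must be in [0, 1]")
    if lr < 0:
        raise ValueError("likelihood ratio must be non-negative")
    if pretest in (0.0, 1.0):
        warnings.warn("degenerate pre-test probability returned unchanged",
                      stacklevel=2)
        return pretest
    if math.isinf(lr):
        return 1.0
    odds = pretest / (1.0 - pretest) * lr
    return odds / (1.0 + odds)


@dataclass(frozen=True)
class RiskReport:
    """Per-subject risk summary combining the lymphocyte test and ApoE4."""

    subject_id: str
    probability_ly_test: float
    lr_positive: float
    pretest: float
    posttest_ly: float
    posttest_apoe: float | None
    posttest_combined: float | None
    decision: bool


def risk_report(results: DiagnosticResults, roc: ROCCurve, subject_id: str,
                features: pd.DataFrame, age: float, apoe4: bool | None = None, *,
                cutoff: float = 0.5, prevalence_model: PrevalenceModel | None = None,
                lr_apoe4_pos: float | None = None,
                lr_apoe4_neg: float | None = None) -> RiskReport:
    """Full Bayesian risk report for one subject.

    ApoE post-test probabilities need published likelihood ratios supplied by
    the caller (``lr_apoe4_pos`` for carriers, ``lr_apoe4_neg`` otherwise);
    they are combined with the lymphocyte LR by sequential odds updates.
    """
    p = float(results.predict(features)[0])
    lr = lr_at_score(roc, p)
    pre = pretest_probability(age, prevalence_model)
    post_ly = posttest_probability(pre, lr)
    post_apoe = post_comb = None
    if apoe4 is not None and lr_apoe4_pos is not None and lr_apoe4_neg is not None:
        lr_apoe = lr_apoe4_pos if apoe4 else lr_apoe4_neg
        post_apoe = posttest_probability(pre, lr_apoe)
        post_comb = posttest_probability(post_apoe, lr)
    return RiskReport(subject_id=subject_id, probability_ly_test=p,
                      lr_positive=lr, pretest=pre, posttest_ly=post_ly,
                      posttest_apoe=post_apoe, posttest_combined=post_comb,
                      decision=p > cutoff)


def validate_frozen(results: DiagnosticResults, features: pd.DataFrame,
                    labels, *, cohort_id: str, subject_ids=None,
                    cutoff: float = 0.5) -> dict:
    """Apply a frozen model to an independent cohort — no refitting.

    Refuses overlapping cohorts (by subject id when available, else by
    cohort id).  Returns the confusion table, accuracy and AUC at the
    stated cut-off, recording both cohort ids.
    """
    y = np.asarray(labels, dtype=float)
    if y.size == 0:
        raise ValueError("validation cohort is empty")
    if subject_ids is not None and results.model is not None:
        overlap = set(subject_ids) & set(results.model.subject_ids)
        if overlap:
            raise ValueError(f"cohort overlap detected: {sorted(overlap)[:5]}")
    elif cohort_id == results.cohort_id:
        raise ValueError("validation cohort id equals training cohort id")
    scores = results.predict(features)
    roc = roc_analysis(scores, y, n_boot=200, seed=0)
    table = operating_point(roc, cutoff)
    return {"training_cohort": results.cohort_id, "validation_cohort": cohort_id,
            "confusion": table, "accuracy": table.accuracy, "auc": roc.auc,
            "sensitivity": table.sensitivity, "specificity": table.specificity}
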