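"""Predictive modelling: logistic regression, ROC, DeLong, bootstrap
validation, calibration and decision-curve analysis.

The positive class throughout is SCC; the model's output is P(SCC).

The logistic solver is Newton/IRLS with Wald standard errors from the
observed information, an explicit rank check (collinearity is reported, not
silently absorbed) and perfect-separation detection that names the
offending predictor.  Empirical AUC is the concordance probability with
half credit for ties, which makes it exactly U/(n1*n2) of the Mann-Whitney
statistic on the same data; the AUC variance and the paired AUC comparison
use DeLong's structural components computed from midranks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.calibration import calibration_curve as _sk_calibration_curve

from .exceptions import (
    CollinearityError,
    ConvergenceError,
    InvalidInputError,
    SeparationError,
)

_Z95 = 1.959963984540054


# --------------------------------------------------------------------------
# logistic regression


class LogisticSubtypeClassifier(BaseEstimator, ClassifierMixin):
    """Maximum-likelihood logistic regression via IRLS.

    Parameters
    ----------
    tol : float
        Convergence tolerance on the gradient infinity norm.
    max_iter : int
        Maximum Newton iterations.
    on_separation : {"raise", "ignore"}
        With "raise" (default) perfect separation aborts the fit with an
        error naming the offending predictor.  "ignore" accepts the
        saturated solution; the predicted ranking is still well defined
        (used by bootstrap validation), the coefficients are not
        interpretable.

    Attributes (after ``fit``)
    --------------------------
    coef_ : ndarray (n_features,) — log-odds slopes.
    intercept_ : float
    se_ : ndarray (n_features + 1,) — Wald SEs, intercept first.
    odds_ratios_, or_ci_ : per-predictor OR and Wald 95% CI.
    p_values_ : Wald two-sided p per predictor (intercept excluded).
    n_iter_ : int; converged_ : bool; feature_names_ : list of str.
    """

    def __init__(self, tol: float = 1e-8, max_iter: int = 100,
                 on_separation: str = "raise"):
        self.tol = tol
        self.max_iter = max_iter
        self.on_separation = on_separation

    def fit(self, X, y, feature_names=None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise InvalidInputError("outcome must contain exactly two classes")
        yb = (y == self.classes_[1]).astype(float)

        names = (
            list(feature_names)
            if feature_names is not None
            else [f"x{i}" for i in range(X.shape[1])]
        )
        if len(names) != X.shape[1]:
            raise InvalidInputError("feature_names length mismatch")

        if np.any(np.ptp(X, axis=0) == 0):
            const = names[int(np.argmax(np.ptp(X, axis=0) == 0))]
            raise CollinearityError(f"constant predictor column: {const!r}")
        design = np.column_stack([np.ones(len(X)), X])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise CollinearityError(
                f"design matrix is rank deficient (collinear predictors "
                f"among {names})"
            )

        beta = np.zeros(design.shape[1])
        trace = []
        converged = False
        for it in range(1, self.max_iter + 1):
            eta = design @ beta
            p = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
            grad = design.T @ (yb - p)
            gnorm = float(np.max(np.abs(grad)))
            trace.append((it, gnorm))
            if gnorm <= self.tol:
                converged = True
                break
            w = p * (1 - p)
            strict = self.on_separation == "raise"
            if strict:
                self._check_separation(eta, yb, names, X)
            hess = design.T @ (design * w[:, None])
            try:
                step = np.linalg.solve(hess, grad)
            except np.linalg.LinAlgError:
                if strict:
                    self._check_separation(eta, yb, names, X, force=True)
                    raise ConvergenceError("singular information matrix",
                                           trace)
                break  # accept the saturated solution
            beta = beta + step
        else:
            it = self.max_iter
        if not converged:
            if self.on_separation == "raise":
                self._check_separation(design @ beta, yb, names, X,
                                       force=True)
                raise ConvergenceError(
                    f"IRLS did not converge in {self.max_iter} iterations "
                    f"(last gradient norm {trace[-1][1]:.3g})",
                    trace,
                )
            warnings.warn("IRLS stopped before convergence "
                          "(separation tolerated)")

        if self.on_separation == "raise":
            # a separated likelihood can also "converge" numerically once
            # the probabilities saturate; re-check at the solution
            self._check_separation(design @ beta, yb, names, X, force=True)

        p = 1.0 / (1.0 + np.exp(-np.clip(design @ beta, -500, 500)))
        w = p * (1 - p)
        info = design.T @ (design * w[:, None])
        try:
            cov = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(info)
        with np.errstate(over="ignore"):
            se = np.sqrt(np.abs(np.diag(cov)))

        self.feature_names_ = names
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:].copy()
        self.se_ = se
        self.n_iter_ = it
        self.converged_ = converged
        z = beta[1:] / se[1:]
        self.wald_z_ = z
        self.p_values_ = 2 * sps.norm.sf(np.abs(z))
        with np.errstate(over="ignore"):
            self.odds_ratios_ = np.exp(beta[1:])
            self.or_ci_ = np.exp(
                np.column_stack([beta[1:] - _Z95 * se[1:],
                                 beta[1:] + _Z95 * se[1:]])
            )
        return self

    @staticmethod
    def _check_separation(eta, yb, names, X, force=False):
        big = np.max(np.abs(eta)) > 30 if len(eta) else False
        if not (big or force):
            return
        pred = eta > 0
        if np.array_equal(pred, yb.astype(bool)) and np.min(np.abs(eta)) > 5:
            # name the predictor that on its own best separates the classes
            best, best_name = -1.0, names[0]
            n = len(yb)
            for j, nm in enumerate(names):
                order = np.argsort(X[:, j], kind="mergesort")
                ys = yb[order]
                cum_pos = np.concatenate([[0.0], np.cumsum(ys)])
                cum_neg = np.arange(n + 1) - cum_pos
                total_pos = ys.sum()
                # best single-threshold accuracy on column j, either direction
                acc_up = (cum_neg + (total_pos - cum_pos)) / n
                acc_dn = (cum_pos + ((n - total_pos) - cum_neg)) / n
                score = float(max(acc_up.max(), acc_dn.max()))
                if score > best:
                    best, best_name = score, nm
            raise SeparationError(best_name)

    def decision_function(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return self.intercept_ + X @ self.coef_

    def predict_proba(self, X):
        p1 = 1.0 / (1.0 + np.exp(-np.clip(self.decision_function(X),
                                          -500, 500)))
        return np.column_stack([1 - p1, p1])

    def predict(self, X):
        return self.classes_[(self.decision_function(X) > 0).astype(int)]

    def summary(self) -> pd.DataFrame:
        """Per-predictor coefficients, ORs, Wald CIs and p-values."""
        return pd.DataFrame(
            {
                "predictor": self.feature_names_,
                "coef": self.coef_,
                "se": self.se_[1:],
                "odds_ratio": self.odds_ratios_,
                "or_ci_low": self.or_ci_[:, 0],
                "or_ci_high": self.or_ci_[:, 1],
                "z": self.wald_z_,
                "p_value": self.p_values_,
            }
        )


def logistic_fit(X, y, feature_names=None, tol=1e-8, max_iter=100):
    """Fit a logistic model; thin functional wrapper over the estimator."""
    return LogisticSubtypeClassifier(tol=tol, max_iter=max_iter).fit(
        X, y, feature_names=feature_names
    )


def univariate_screen(
    cohort: pd.DataFrame,
    candidates: list[str],
    outcome: np.ndarray,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One single-predictor logistic fit per candidate.

    Returns OR, Wald CI and p per candidate plus a boolean ``passed``
    column at the given alpha.  Per-candidate separation failures are
    recorded (OR columns NaN, ``error`` filled) without aborting the screen.
    """
    rows = []
    for name in candidates:
        if name not in cohort.columns:
            raise InvalidInputError(f"candidate {name!r} not in cohort")
        try:
            m = logistic_fit(
                cohort[[name]].to_numpy(), outcome, feature_names=[name]
            )
            rows.append(
                dict(
                    predictor=name,
                    odds_ratio=m.odds_ratios_[0],
                    or_ci_low=m.or_ci_[0, 0],
                    or_ci_high=m.or_ci_[0, 1],
                    p_value=m.p_values_[0],
                    passed=bool(m.p_values_[0] < alpha),
                    error="",
                )
            )
        except (SeparationError, CollinearityError, ConvergenceError) as exc:
            rows.append(
                dict(
                    predictor=name, odds_ratio=np.nan, or_ci_low=np.nan,
                    or_ci_high=np.nan, p_value=np.nan, passed=False,
                    error=str(exc),
                )
            )
    return pd.DataFrame(rows)


def multivariate_fit(
    cohort: pd.DataFrame,
    predictors: list[str],
    outcome: np.ndarray,
    elimination: str = "none",
    alpha: float = 0.05,
) -> LogisticSubtypeClassifier:
    """Joint logistic fit on the passed candidates.

    ``elimination="backward"`` repeatedly drops the largest-p predictor
    above alpha and refits until all remaining predictors are significant
    (at least one predictor is always retained).
    """
    if elimination not in {"none", "backward"}:
        raise InvalidInputError(f"unknown elimination {elimination!r}")
    if not predictors:
        raise InvalidInputError("need at least one predictor")
    kept = list(predictors)
    while True:
        model = logistic_fit(
            cohort[kept].to_numpy(), outcome, feature_names=kept
        )
        if elimination == "none" or len(kept) == 1:
            return model
        worst = int(np.argmax(model.p_values_))
        if model.p_values_[worst] <= alpha:
            return model
        kept.pop(worst)


# --------------------------------------------------------------------------
# ROC / DeLong


@dataclass(frozen=True)
class ROCResult:
    auc: float
    ci_low: float
    ci_high: float
    cutoff: float
    sensitivity: float
    specificity: float
    operating_points: pd.DataFrame = field(repr=False, compare=False,
                                           default=None)


@dataclass(frozen=True)
class DeLongComparison:
    auc_a: float
    auc_b: float
    delta: float
    z: float
    p_value: float


def _placements(pos: np.ndarray, neg: np.ndarray):
    """Midrank placement values: V10 (per positive) and V01 (per negative).

    ``V10[i] = P(neg < pos_i) + 0.5 P(neg == pos_i)`` and symmetrically for
    V01; their common mean is the empirical AUC with tie credit 0.5.
    """
    m, n = len(pos), len(neg)
    all_ranks = sps.rankdata(np.concatenate([pos, neg]))
    pos_ranks = sps.rankdata(pos)
    neg_ranks = sps.rankdata(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    return v10, v01


def empirical_auc(scores, labels, positive=1) -> float:
    """Concordance-probability AUC with half credit for ties."""
    scores = np.asarray(scores, float)
    y = np.asarray(labels) == positive
    pos, neg = scores[y], scores[~y]
    if len(pos) == 0 or len(neg) == 0:
        raise InvalidInputError("both classes must be present")
    v10, _ = _placements(pos, neg)
    return float(v10.mean())


def roc_analysis(scores, labels, positive=1) -> ROCResult:
    """Empirical ROC with DeLong CI and the Youden-optimal cutoff.

    Cutoffs are taken midway between adjacent observed scores (plus the two
    open ends); a case is called positive when its score is >= the cutoff.
    Among cutoffs attaining the maximal Youden J the one with the highest
    sensitivity is reported.
    """
    scores = np.asarray(scores, float)
    y = np.asarray(labels) == positive
    pos, neg = scores[y], scores[~y]
    if len(pos) == 0 or len(neg) == 0:
        raise InvalidInputError("both classes must be present")

    v10, v01 = _placements(pos, neg)
    auc = float(v10.mean())
    var = (np.var(v10, ddof=1) / len(pos) if len(pos) > 1 else 0.0) + (
        np.var(v01, ddof=1) / len(neg) if len(neg) > 1 else 0.0
    )
    se = float(np.sqrt(var))
    ci_low, ci_high = np.clip([auc - _Z95 * se, auc + _Z95 * se], 0.0, 1.0)

    uniq = np.unique(scores)
    cuts = np.concatenate(
        [[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2, [uniq[-1] + 1.0]]
    )
    sens = np.array([(pos >= c).mean() for c in cuts])
    spec = np.array([(neg < c).mean() for c in cuts])
    j = sens + spec - 1
    best_j = j.max()
    contenders = np.flatnonzero(np.isclose(j, best_j))
    best = contenders[np.argmax(sens[contenders])]
    table = pd.DataFrame(
        {"cutoff": cuts, "sensitivity": sens, "specificity": spec,
         "youden_j": j}
    )
    return ROCResult(
        auc=auc, ci_low=float(ci_low), ci_high=float(ci_high),
        cutoff=float(cuts[best]), sensitivity=float(sens[best]),
        specificity=float(spec[best]), operating_points=table,
    )


def delong_test(scores_a, scores_b, labels, positive=1) -> DeLongComparison:
    """Paired DeLong comparison of two AUCs on the same cases."""
    scores_a = np.asarray(scores_a, float)
    scores_b = np.asarray(scores_b, float)
    y = np.asarray(labels) == positive
    if len(scores_a) != len(scores_b) or len(scores_a) != len(y):
        raise InvalidInputError("scores must be paired on identical cases")
    if y.all() or not y.any():
        raise InvalidInputError("both classes must be present")

    v10 = np.empty((2, int(y.sum())))
    v01 = np.empty((2, int((~y).sum())))
    for k, s in enumerate((scores_a, scores_b)):
        v10[k], v01[k] = _placements(s[y], s[~y])
    aucs = v10.mean(axis=1)
    m, n = v10.shape[1], v01.shape[1]
    s10 = np.cov(v10) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(v01) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_delta = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    delta = float(aucs[0] - aucs[1])
    if var_delta <= 0:
        z = 0.0 if np.isclose(delta, 0) else np.inf * np.sign(delta)
    else:
        z = delta / float(np.sqrt(var_delta))
    p = float(2 * sps.norm.sf(abs(z))) if np.isfinite(z) else 0.0
    if np.isclose(delta, 0):
        z, p = 0.0, 1.0
    return DeLongComparison(float(aucs[0]), float(aucs[1]), delta,
                            float(z), p)


# --------------------------------------------------------------------------
# internal validation


@dataclass(frozen=True)
class ValidationReport:
    apparent_auc: float
    bootstrap_mean_auc: float
    ci_low: float
    ci_high: float
    optimism: float
    corrected_auc: float
    n_resamples: int
    n_failed: int
    seed: int


def bootstrap_validate(
    cohort: pd.DataFrame,
    predictors: list[str],
    outcome: np.ndarray,
    B: int = 1000,
    seed: int = 0,
) -> ValidationReport:
    """Optimism-corrected bootstrap validation of a logistic model.

    For each of ``B`` resamples (with replacement, stratified by outcome so
    both classes are always present) the model is refitted; its AUC on the
    resample minus its AUC on the original cohort estimates the optimism.
    ``corrected = apparent - mean(optimism)``.  Deterministic given seed.
    At least 95% of resamples must fit successfully.
    """
    if B < 1:
        raise InvalidInputError("B must be >= 1")
    y = np.asarray(outcome).astype(bool)
    X = cohort[predictors].to_numpy()
    apparent_model = logistic_fit(X, y.astype(int), feature_names=predictors)
    apparent = empirical_auc(apparent_model.predict_proba(X)[:, 1], y, True)

    rng = np.random.default_rng(seed)
    idx_pos, idx_neg = np.flatnonzero(y), np.flatnonzero(~y)
    boot_aucs, optimisms = [], []
    failed = 0
    for _ in range(B):
        take = np.concatenate(
            [rng.choice(idx_pos, len(idx_pos), replace=True),
             rng.choice(idx_neg, len(idx_neg), replace=True)]
        )
        Xb, yb = X[take], y[take]
        try:
            # only the predicted ranking enters the AUC, so resample
            # refits tolerate separation instead of aborting
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = LogisticSubtypeClassifier(on_separation="ignore").fit(
                    Xb, yb.astype(int), feature_names=predictors
                )
        except (SeparationError, CollinearityError, ConvergenceError) as exc:
            failed += 1
            warnings.warn(f"bootstrap replicate failed: {exc}")
            continue
        auc_b = empirical_auc(m.predict_proba(Xb)[:, 1], yb, True)
        auc_o = empirical_auc(m.predict_proba(X)[:, 1], y, True)
        boot_aucs.append(auc_b)
        optimisms.append(auc_b - auc_o)
    if failed > 0.05 * B:
        raise ConvergenceError(
            f"{failed}/{B} bootstrap replicates failed to fit"
        )
    boot_aucs = np.asarray(boot_aucs)
    optimism = float(np.mean(optimisms))
    lo, hi = np.percentile(boot_aucs, [2.5, 97.5])
    return ValidationReport(
        apparent_auc=float(apparent),
        bootstrap_mean_auc=float(boot_aucs.mean()),
        ci_low=float(lo), ci_high=float(hi),
        optimism=optimism,
        corrected_auc=float(apparent - optimism),
        n_resamples=B - failed, n_failed=failed, seed=seed,
    )


# --------------------------------------------------------------------------
# calibration and decision curves


@dataclass(frozen=True)
class CalibrationResult:
    curve: pd.DataFrame
    slope: float
    intercept: float
    n_bins: int


def calibration_curve(predicted, outcomes, bins: int = 10) -> CalibrationResult:
    """Equal-count calibration curve plus logistic recalibration.

    The recalibration slope/intercept come from a logistic fit of the
    outcomes on ``logit(predicted)``; a perfectly calibrated model has
    slope 1 and intercept 0.  With (near-)constant predictions the slope is
    undefined and returned as NaN.
    """
    p = np.asarray(predicted, float)
    y = np.asarray(outcomes).astype(int)
    if np.any(p <= 0) or np.any(p >= 1):
        raise InvalidInputError("predictions must lie strictly in (0, 1)")
    n_bins = min(bins, len(np.unique(p)))
    if n_bins < bins:
        warnings.warn(
            f"reduced calibration bins from {bins} to {n_bins} "
            "(too few distinct predictions)"
        )
    frac_pos, mean_pred = _sk_calibration_curve(
        y, p, n_bins=n_bins, strategy="quantile"
    )
    curve = pd.DataFrame({"mean_predicted": mean_pred,
                          "observed_frequency": frac_pos})
    logit = np.log(p / (1 - p))
    if np.ptp(logit) < 1e-12:
        slope, intercept = float("nan"), float("nan")
    else:
        try:
            m = logistic_fit(logit[:, None], y, feature_names=["logit_p"])
            slope, intercept = float(m.coef_[0]), float(m.intercept_)
        except (SeparationError, ConvergenceError):
            slope, intercept = float("nan"), float("nan")
    return CalibrationResult(curve=curve, slope=slope, intercept=intercept,
                             n_bins=len(curve))


@dataclass(frozen=True)
class DecisionCurve:
    table: pd.DataFrame  # threshold, nb_model, nb_all, nb_none


def decision_curve(predicted, outcomes, thresholds=None) -> DecisionCurve:
    """Net benefit of the model, treat-all and treat-none policies.

    ``NB(pt) = TP/n - (FP/n) * pt / (1 - pt)`` calling a case positive when
    its predicted probability is >= pt.
    """
    p = np.asarray(predicted, float)
    y = np.asarray(outcomes).astype(bool)
    if thresholds is None:
        thresholds = np.arange(0.01, 1.0, 0.01)
    thresholds = np.asarray(thresholds, float)
    if np.any(thresholds <= 0) or np.any(thresholds >= 1):
        raise InvalidInputError("thresholds must lie strictly in (0, 1)")
    n = len(y)
    prev = y.mean()
    rows = []
    for pt in thresholds:
        call = p >= pt
        tp = (call & y).sum() / n
        fp = (call & ~y).sum() / n
        w = pt / (1 - pt)
        rows.append((pt, tp - fp * w, prev - (1 - prev) * w, 0.0))
    return DecisionCurve(
        pd.DataFrame(rows, columns=["threshold", "nb_model", "nb_all",
                                    "nb_none"])
    )
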