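"""Diagnostic performance statistics for benign-vs-malignant classification.

Contents, in workflow order:

* empirical ROC analysis with the Youden-index cutoff and a DeLong-variance
  confidence interval for the AUC;
* the DeLong test for the difference of two correlated (same-subject) AUCs,
  via the structural-component covariance of the fast midrank algorithm
  (Sun & Xu 2014 formulation);
* multivariate logistic regression with single-pass Wald-p feature
  selection, a ridge fallback under perfect separation, and the combined
  ROC of the fitted probability score;
* nomogram construction (per-feature 0–100 point scales, total points →
  probability through the inverse logit);
* Hosmer–Lemeshow goodness of fit over risk-decile bins;
* optimism-corrected (bootstrap) calibration curves;
* decision-curve analysis: net benefit of the model against the treat-all
  and treat-none strategies across threshold probabilities.

Throughout, *malignant* is the positive class.  Markers that are lower in
malignancy (D, β, ADC) are negated internally before ROC analysis and the
cutoff is mapped back to the original scale with the "value ≤ cutoff ⇒
malignant" reading; µ and probability scores use "value ≥ cutoff ⇒
malignant".
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

__all__ = [
    "RocResult",
    "LogisticModel",
    "NomogramSpec",
    "NetBenefitCurve",
    "roc_analysis",
    "delong_test",
    "fit_logistic_with_selection",
    "combined_roc",
    "build_nomogram",
    "hosmer_lemeshow",
    "bootstrap_calibration",
    "decision_curve",
]

logger = logging.getLogger(__name__)

ALPHA = 0.05
_RIDGE_LAMBDA = 1e-4


# ---------------------------------------------------------------------------
# ROC / DeLong
# ---------------------------------------------------------------------------

@dataclass
class RocResult:
    """AUC with DeLong CI and the Youden-optimal operating point.

    ``orientation`` records which direction of the *original* score
    indicates malignancy: ``"lower"`` (classify malignant when value ≤
    cutoff) or ``"higher"`` (value ≥ cutoff).
    """

    auc: float
    auc_ci: Tuple[float, float]
    cutoff: float
    sensitivity: float
    specificity: float
    accuracy: float
    orientation: str


def _check_labels(labels):
    y = np.asarray(labels).astype(bool)
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    return y


def _midrank(x):
    """Midranks (ties averaged), 1-based."""
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    n = len(x)
    t = np.zeros(n)
    i = 0
    while i < n:
        j = i
        while j < n and xs[j] == xs[i]:
            j += 1
        t[i:j] = 0.5 * (i + j - 1) + 1
        i = j
    out = np.empty(n)
    out[order] = t
    return out


def _delong_components(scores, y):
    """AUC and per-subject structural components (V10 positives, V01 negatives).

    ``scores`` oriented so that larger values indicate the positive class.
    """
    pos = scores[y]
    neg = scores[~y]
    m, n = len(pos), len(neg)
    rk_pos = _midrank(pos)
    rk_neg = _midrank(neg)
    rk_all = _midrank(np.concatenate([pos, neg]))
    auc = (rk_all[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (rk_all[:m] - rk_pos) / n
    v01 = 1.0 - (rk_all[m:] - rk_neg) / m
    return auc, v10, v01


def _auc_and_var(scores, y):
    auc, v10, v01 = _delong_components(scores, y)
    var = np.var(v10, ddof=1) / len(v10) + np.var(v01, ddof=1) / len(v01)
    return auc, var


def _orient(scores, y, orientation):
    """Return (internal_scores, resolved_orientation); internal = higher→positive."""
    scores = np.asarray(scores, dtype=float)
    if orientation == "auto":
        auc, _, _ = _delong_components(scores, y)
        orientation = "higher" if auc >= 0.5 else "lower"
    if orientation == "higher":
        return scores, orientation
    if orientation == "lower":
        return -scores, orientation
    raise ValueError(f"unknown orientation {orientation!r}")


def roc_analysis(scores, labels, orientation: str = "auto") -> RocResult:
    """Empirical ROC analysis of one marker.

    Parameters
    ----------
    scores : array-like
        Marker values on their original scale.
    labels : array-like of bool
        True for malignant (the positive class).
    orientation : {"auto", "higher", "lower"}
        Direction of the original score that indicates malignancy;
        ``"auto"`` picks the direction giving AUC ≥ 0.5.

    The cutoff maximizes the Youden index (sensitivity + specificity − 1)
    over midpoints of consecutive distinct score values; ties are broken
    toward higher specificity.  Sensitivity/specificity/accuracy are
    reported in percent at that cutoff.
    """
    y = _check_labels(labels)
    s, orientation = _orient(scores, y, orientation)
    auc, var = _auc_and_var(s, y)
    se = np.sqrt(var)
    z = stats.norm.ppf(1 - ALPHA / 2)
    ci = (max(0.0, auc - z * se), min(1.0, auc + z * se))

    uniq = np.unique(s)
    if uniq.size == 1:
        raise ValueError("scores are constant: no operating point exists")
    cands = 0.5 * (uniq[:-1] + uniq[1:])
    pos, neg = s[y], s[~y]
    sens = np.array([(pos >= c).mean() for c in cands])
    spec = np.array([(neg < c).mean() for c in cands])
    youden = sens + spec - 1.0
    best = np.flatnonzero(np.isclose(youden, youden.max()))
    # among ties, the largest internal cutoff classifies fewest positives →
    # highest specificity
    k = best[np.argmax(spec[best])]
    cut_internal = cands[k]
    tp = (pos >= cut_internal).sum()
    tn = (neg < cut_internal).sum()
    acc = (tp + tn) / len(s) * 100.0

    cutoff = cut_internal if orientation == "higher" else -cut_internal
    return RocResult(auc=float(auc), auc_ci=(float(ci[0]), float(ci[1])),
                     cutoff=float(cutoff), sensitivity=float(sens[k] * 100),
                     specificity=float(spec[k] * 100), accuracy=float(acc),
                     orientation=orientation)


def delong_test(scores_a, scores_b, labels, orientation_a: str = "auto",
                orientation_b: str = "auto") -> Tuple[float, float]:
    """DeLong test for the difference of two correlated AUCs.

    Both score vectors must refer to the same subjects.  Returns ``(z, p)``
    (two-sided).  Identical scores (zero-variance difference with zero AUC
    difference) report ``(0, 1)``; a zero-variance nonzero difference is
    degenerate and raises.
    """
    y = _check_labels(labels)
    sa, _ = _orient(scores_a, y, orientation_a)
    sb, _ = _orient(scores_b, y, orientation_b)
    auc_a, v10a, v01a = _delong_components(sa, y)
    auc_b, v10b, v01b = _delong_components(sb, y)
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.stack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.stack([v01a, v01b]), ddof=1)
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    diff = auc_a - auc_b
    if var_diff <= 0:
        if np.isclose(diff, 0):
            return 0.0, 1.0
        raise ValueError("degenerate DeLong variance with nonzero AUC difference")
    z = diff / np.sqrt(var_diff)
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(p)


# ---------------------------------------------------------------------------
# Logistic model with single-pass Wald selection
# ---------------------------------------------------------------------------

@dataclass
class LogisticModel:
    """A fitted (possibly feature-selected) logistic model."""

    intercept: float
    coef: dict
    pvalues: dict
    retained: list
    fitted_probabilities: np.ndarray
    penalized: bool = False

    def linear_predictor(self, data: pd.DataFrame) -> np.ndarray:
        lp = np.full(len(data), self.intercept)
        for f, c in self.coef.items():
            lp += c * np.asarray(data[f], dtype=float)
        return lp

    def predict_proba(self, data: pd.DataFrame) -> np.ndarray:
        return expit(self.linear_predictor(data))


def _ridge_logistic(X, y, lam=_RIDGE_LAMBDA, max_iter=200, tol=1e-10):
    """Ridge-penalized IRLS fit; penalty on slopes only.

    Returns (params, bse) with Wald SEs from the penalized information
    matrix.  Used when plain maximum likelihood breaks down (perfect
    separation or collinearity).
    """
    n, p = X.shape
    pen = lam * np.eye(p)
    pen[0, 0] = 0.0  # intercept unpenalized
    beta = np.zeros(p)
    for _ in range(max_iter):
        mu = expit(X @ beta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        grad = X.T @ (y - mu) - pen @ beta
        hess = X.T @ (X * w[:, None]) + pen
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    mu = expit(X @ beta)
    w = np.clip(mu * (1 - mu), 1e-10, None)
    hess = X.T @ (X * w[:, None]) + pen
    bse = np.sqrt(np.diag(np.linalg.inv(hess)))
    return beta, bse


def _fit_logit(X: np.ndarray, y: np.ndarray):
    """ML logistic fit with ridge fallback; returns (params, bse, penalized)."""
    import statsmodels.api as sm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
            ok = (res.mle_retvals.get("converged", False)
                  and np.all(np.isfinite(res.bse))
                  and np.max(np.abs(res.params)) < 50)
        except Exception:
            ok = False
        if ok:
            return np.asarray(res.params), np.asarray(res.bse), False
    logger.warning("logistic ML fit degenerate (separation or collinearity); "
                   "falling back to ridge (lambda=%g)", _RIDGE_LAMBDA)
    beta, bse = _ridge_logistic(X, y)
    return beta, bse, True


def fit_logistic_with_selection(data: pd.DataFrame, labels,
                                features: Sequence[str] = ("D", "beta", "mu"),
                                alpha: float = ALPHA) -> LogisticModel:
    """Multivariate logistic fit with one-step Wald-p exclusion.

    Fits labels ~ features, drops every feature with Wald p ≥ ``alpha`` and
    refits once on the survivors (an intercept-only model if none survive).
    """
    y = _check_labels(labels).astype(float)
    features = list(features)

    def fit(feats):
        X = np.column_stack([np.ones(len(data))] +
                            [np.asarray(data[f], dtype=float) for f in feats])
        params, bse, penalized = _fit_logit(X, y)
        zvals = params / bse
        pvals = 2 * stats.norm.sf(np.abs(zvals))
        return params, pvals, penalized, X

    params, pvals, penalized, X = fit(features)
    retained = [f for f, p in zip(features, pvals[1:]) if p < alpha]
    if retained != features:
        params, pvals, penalized, X = fit(retained)

    probs = expit(X @ params)
    return LogisticModel(
        intercept=float(params[0]),
        coef={f: float(c) for f, c in zip(retained, params[1:])},
        pvalues={f: float(p) for f, p in zip(retained, pvals[1:])},
        retained=retained,
        fitted_probabilities=probs,
        penalized=penalized,
    )


def combined_roc(model: LogisticModel, data: pd.DataFrame, labels) -> RocResult:
    """ROC of the model's fitted probability score (cutoff on probability scale)."""
    probs = model.predict_proba(data)
    return roc_analysis(probs, labels, orientation="higher")


# ---------------------------------------------------------------------------
# Nomogram
# ---------------------------------------------------------------------------

@dataclass
class NomogramSpec:
    """Point scales of a logistic nomogram.

    The feature with the largest |coefficient| × observed range spans 0–100
    points; other features are scaled proportionally.  For each feature the
    reference value (0 points) is the end of its observed range that
    contributes least to the malignancy risk, so point maps are monotone
    non-decreasing in risk.
    """

    lp_per_point: float
    base_lp: float
    coef: dict
    ref: dict
    value_range: dict

    def feature_points(self, feature: str, value) -> np.ndarray:
        c = self.coef[feature]
        return (c * (np.asarray(value, dtype=float) - self.ref[feature])
                / self.lp_per_point)

    def total_points(self, data: pd.DataFrame) -> np.ndarray:
        return sum(self.feature_points(f, data[f]) for f in self.coef)

    def probability(self, total_points) -> np.ndarray:
        return expit(self.base_lp + np.asarray(total_points, dtype=float)
                     * self.lp_per_point)


def build_nomogram(model: LogisticModel, data: pd.DataFrame) -> NomogramSpec:
    """Derive the nomogram point scales from a fitted model and a cohort."""
    if not model.coef:
        raise ValueError("cannot build a nomogram from an intercept-only model")
    ranges, refs = {}, {}
    for f, c in model.coef.items():
        lo, hi = float(np.min(data[f])), float(np.max(data[f]))
        ranges[f] = (lo, hi)
        refs[f] = lo if c > 0 else hi  # 0-point end = least risky
    spans = {f: abs(c) * (ranges[f][1] - ranges[f][0]) for f, c in model.coef.items()}
    lp_per_point = max(spans.values()) / 100.0
    if lp_per_point == 0:
        raise ValueError("all retained features are constant")
    base_lp = model.intercept + sum(c * refs[f] for f, c in model.coef.items())
    return NomogramSpec(lp_per_point=lp_per_point, base_lp=base_lp,
                        coef=dict(model.coef), ref=refs, value_range=ranges)


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def hosmer_lemeshow(probabilities, labels, g: int = 10) -> Tuple[float, float]:
    """Hosmer–Lemeshow chi-square over ``g`` risk-decile bins.

    Returns ``(chi2, p)`` with ``g_eff − 2`` degrees of freedom, where bins
    emptied by ties are merged into their neighbors (with a warning).
    """
    if g < 3:
        raise ValueError("need at least 3 bins")
    p = np.asarray(probabilities, dtype=float)
    y = _check_labels(labels).astype(float)
    bins = pd.qcut(p, q=g, labels=False, duplicates="drop")
    g_eff = int(bins.max()) + 1
    if g_eff < g:
        logger.warning("merged %d empty/tied Hosmer-Lemeshow bins", g - g_eff)
    if g_eff < 3:
        raise ValueError("too few distinct risk bins")
    chi2 = 0.0
    for k in range(g_eff):
        sel = bins == k
        nk = sel.sum()
        o1 = y[sel].sum()
        e1 = p[sel].sum()
        vk = e1 * (1 - e1 / nk)
        chi2 += (o1 - e1) ** 2 / max(vk, 1e-12)
    df = g_eff - 2
    return float(chi2), float(stats.chi2.sf(chi2, df))


def bootstrap_calibration(model: LogisticModel, data: pd.DataFrame, labels,
                          n_boot: int = 200, g: int = 10,
                          seed: int = 0) -> pd.DataFrame:
    """Optimism-corrected calibration curve over risk-decile bins.

    For each bootstrap resample the model formula is refitted and the
    apparent-minus-test difference of per-bin observed frequencies is
    accumulated; the mean optimism is subtracted from the apparent curve.
    Returns a DataFrame with columns ``predicted``, ``observed``,
    ``observed_corrected`` (one row per bin).
    """
    if n_boot < 100:
        raise ValueError("need at least 100 bootstrap replicates")
    y = _check_labels(labels).astype(float)
    rng = np.random.default_rng(seed)
    probs = model.predict_proba(data)
    edges = np.quantile(probs, np.linspace(0, 1, g + 1))
    edges[0], edges[-1] = 0.0, 1.0
    edges = np.unique(edges)

    def curve(p_vec, y_vec):
        idx = np.clip(np.searchsorted(edges, p_vec, side="right") - 1,
                      0, len(edges) - 2)
        pred = np.full(len(edges) - 1, np.nan)
        obs = np.full(len(edges) - 1, np.nan)
        for k in range(len(edges) - 1):
            sel = idx == k
            if sel.any():
                pred[k] = p_vec[sel].mean()
                obs[k] = y_vec[sel].mean()
        return pred, obs

    pred_app, obs_app = curve(probs, y)
    feats = model.retained
    optimism = np.zeros_like(obs_app)
    counts = np.zeros_like(obs_app)
    n = len(data)
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        d_b = data.iloc[idx].reset_index(drop=True)
        y_b = y[idx]
        if y_b.all() or not y_b.any():
            continue
        m_b = fit_logistic_with_selection(d_b, y_b.astype(bool),
                                          features=feats, alpha=1.0)
        _, obs_boot = curve(m_b.predict_proba(d_b), y_b)
        _, obs_orig = curve(m_b.predict_proba(data), y)
        valid = ~np.isnan(obs_boot) & ~np.isnan(obs_orig)
        optimism[valid] += obs_boot[valid] - obs_orig[valid]
        counts[valid] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_opt = np.where(counts > 0, optimism / np.maximum(counts, 1), 0.0)
    out = pd.DataFrame({
        "predicted": pred_app,
        "observed": obs_app,
        "observed_corrected": np.clip(obs_app - mean_opt, 0.0, 1.0),
    }).dropna().reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# Decision-curve analysis
# ---------------------------------------------------------------------------

@dataclass
class NetBenefitCurve:
    """Net benefit of the model vs treat-all/treat-none over thresholds."""

    thresholds: np.ndarray
    net_benefit: np.ndarray
    treat_all: np.ndarray
    treat_none: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.treat_none is None:
            self.treat_none = np.zeros_like(self.thresholds)


DEFAULT_DCA_THRESHOLDS = np.round(np.arange(0.01, 1.00, 0.01), 2)


def decision_curve(probabilities, labels,
                   thresholds=DEFAULT_DCA_THRESHOLDS) -> NetBenefitCurve:
    """Decision-curve analysis.

    ``NB(p_t) = TP/n − FP/n · p_t/(1−p_t)`` where a subject is treated when
    its predicted probability ≥ p_t; treat-all has TP = all positives and
    FP = all negatives; treat-none is identically zero.
    """
    p = np.asarray(probabilities, dtype=float)
    y = _check_labels(labels)
    t = np.asarray(thresholds, dtype=float)
    if np.any((t <= 0) | (t >= 1)):
        raise ValueError("thresholds must lie strictly inside (0, 1)")
    n = len(p)
    prev = y.mean()
    odds = t / (1 - t)
    nb = np.empty_like(t)
    for i, pt in enumerate(t):
        treat = p >= pt
        tp = (treat & y).sum() / n
        fp = (treat & ~y).sum() / n
        nb[i] = tp - fp * odds[i]
    treat_all = prev - (1 - prev) * odds
    return NetBenefitCurve(thresholds=t, net_benefit=nb, treat_all=treat_all)
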