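"""Cohort-level statistics: paired t-test, ROC/AUC with DeLong inference,
Pearson correlation, logistic regression and balanced sub-sampling.

Everything is two-sided at the 95% confidence level. The ROC operating
point uses the strict >25% increase rule (see :mod:`kernem.metrics`), with
higher increase scoring as "more positive". AUC inference follows DeLong's
structural-components construction for correlated ROC curves, implemented
here with midranks; standard tests (paired t, Pearson) and the logistic
maximum-likelihood fit are delegated to scipy/statsmodels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.stats as st
import statsmodels.api as sm
from sklearn.metrics import roc_curve

from .errors import ContractError, StatisticError
from .metrics import EORTC_THRESHOLD, classify

__all__ = [
    "PairedTestResult",
    "RocResult",
    "LogisticFit",
    "paired_t_test",
    "roc_analysis",
    "delong_test",
    "delong_auc_variance",
    "pearson_correlation",
    "logistic_fit",
    "balanced_subsample",
]


@dataclass
class PairedTestResult:
    t_statistic: float
    df: int
    p_value: float
    mean_difference: float


@dataclass
class RocResult:
    """ROC sweep plus summary metrics at the clinical operating point."""

    thresholds: np.ndarray
    sensitivity: np.ndarray  # TPR along the sweep
    specificity: np.ndarray  # 1 - FPR along the sweep
    auc: float
    auc_variance: float  # DeLong estimate
    operating_threshold: float
    sensitivity_at_threshold: float
    specificity_at_threshold: float
    accuracy_at_threshold: float
    precision_at_threshold: float


@dataclass
class LogisticFit:
    """logit P(positive) = beta0 + beta1 * TBR_max."""

    intercept: float
    slope: float
    intercept_se: float
    slope_se: float
    intercept_p: float
    slope_p: float
    residual_deviance: float
    converged: bool
    classification_threshold: float | None  # -beta0/beta1, probability-0.5 TBR
    accuracy_in_sample: float | None = None
    diagnostic: str = ""


def _as_bool_labels(labels) -> np.ndarray:
    labels = np.asarray(labels).astype(bool)
    if labels.ndim != 1:
        raise ContractError("labels must be 1-D")
    return labels


def paired_t_test(x: Sequence[float], y: Sequence[float]) -> PairedTestResult:
    """Classical paired t-test on per-subject differences (two-sided).

    Degenerate cases: identical vectors give t=0, p=1; zero-variance
    differences with nonzero mean give an infinite t and p=0.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ContractError("need two equal-length 1-D samples with n >= 2")
    d = x - y
    n = len(d)
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        if mean == 0.0:
            return PairedTestResult(0.0, n - 1, 1.0, 0.0)
        t = np.inf if mean > 0 else -np.inf
        return PairedTestResult(float(t), n - 1, 0.0, mean)
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * st.t.sf(abs(t), df=n - 1)
    return PairedTestResult(float(t), n - 1, float(p), mean)


def _midrank(x: np.ndarray) -> np.ndarray:
    return st.rankdata(x, method="average")


def _delong_placements(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and the DeLong structural components V10 (positives), V01 (negatives)."""
    pos = scores[labels]
    neg = scores[~labels]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise StatisticError("both classes must be present")
    all_ranks = _midrank(np.concatenate([pos, neg]))
    pos_ranks = _midrank(pos)
    neg_ranks = _midrank(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    auc = float(v10.mean())
    return auc, v10, v01


def delong_auc_variance(scores, labels) -> tuple[float, float]:
    """(AUC, DeLong variance) for a single ROC curve."""
    labels = _as_bool_labels(labels)
    scores = np.asarray(scores, float)
    auc, v10, v01 = _delong_placements(scores, labels)
    m, n = len(v10), len(v01)
    s10 = float(np.var(v10, ddof=1)) if m > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if n > 1 else 0.0
    return auc, s10 / m + s01 / n


def delong_test(scores_1, scores_2, labels) -> float:
    """Two-sided p-value for AUC(scores_1) != AUC(scores_2), same subjects.

    Uses the covariance of the structural components, so the correlation
    between the two ROC curves is accounted for. Identical score vectors
    give p = 1; a zero variance estimate with a nonzero AUC difference is
    flagged as a :class:`StatisticError`.
    """
    labels = _as_bool_labels(labels)
    s1 = np.asarray(scores_1, float)
    s2 = np.asarray(scores_2, float)
    if s1.shape != s2.shape or s1.shape != labels.shape:
        raise ContractError("score vectors and labels must be aligned")
    auc1, v10_1, v01_1 = _delong_placements(s1, labels)
    auc2, v10_2, v01_2 = _delong_placements(s2, labels)
    m, n = len(v10_1), len(v01_1)
    diff = auc1 - auc2
    if m < 2 or n < 2:
        raise StatisticError("need >= 2 subjects per class for DeLong variance")
    s10 = np.cov(np.vstack([v10_1, v10_2]), ddof=1)
    s01 = np.cov(np.vstack([v01_1, v01_2]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    if var <= 0:
        if diff == 0:
            return 1.0
        raise StatisticError("zero DeLong variance with nonzero AUC difference")
    z = diff / np.sqrt(var)
    return float(2.0 * st.norm.sf(abs(z)))


def roc_analysis(
    scores, labels, threshold: float = EORTC_THRESHOLD
) -> RocResult:
    """ROC sweep with DeLong AUC variance and operating-point summary.

    ``scores`` are the percentage uptake increases; higher means more
    positive. The operating point applies the strict >threshold rule.
    """
    labels = _as_bool_labels(labels)
    scores = np.asarray(scores, float)
    if scores.shape != labels.shape:
        raise ContractError("scores and labels must be aligned")
    if labels.all() or not labels.any():
        raise StatisticError("ROC requires both classes")
    fpr, tpr, thresholds = roc_curve(labels, scores)
    auc, var = delong_auc_variance(scores, labels)

    pred = np.array([classify(s, threshold) for s in scores])
    tp = int(np.sum(pred & labels))
    tn = int(np.sum(~pred & ~labels))
    fp = int(np.sum(pred & ~labels))
    fn = int(np.sum(~pred & labels))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    acc = (tp + tn) / len(labels)
    prec = tp / (tp + fp) if (tp + fp) > 0 else float("nan")
    return RocResult(
        thresholds=thresholds,
        sensitivity=tpr,
        specificity=1.0 - fpr,
        auc=auc,
        auc_variance=var,
        operating_threshold=float(threshold),
        sensitivity_at_threshold=float(sens),
        specificity_at_threshold=float(spec),
        accuracy_at_threshold=float(acc),
        precision_at_threshold=float(prec),
    )


def pearson_correlation(x, y) -> tuple[float, float]:
    """Pearson r and two-sided p (t-distribution with n-2 df)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ContractError("x and y must be equal-length 1-D vectors")
    if len(x) < 3:
        raise StatisticError("Pearson correlation needs n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise StatisticError("constant input: correlation undefined")
    res = st.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def logistic_fit(tbr, labels) -> LogisticFit:
    """ML logistic regression of positivity on TBR_max.

    Wald standard errors and p-values come from the observed information;
    residual deviance is -2 log-likelihood (saturated Bernoulli model has
    deviance 0). ``classification_threshold`` is the TBR at which the
    fitted probability crosses 0.5, -beta0/beta1; it is None when the fit
    failed or the slope vanishes. Perfect separation is flagged as a
    non-converged fit, never reported as valid estimates.
    """
    labels = _as_bool_labels(labels).astype(float)
    tbr = np.asarray(tbr, float)
    if tbr.shape != labels.shape:
        raise ContractError("tbr and labels must be aligned")
    if labels.all() or not labels.any():
        raise StatisticError("logistic fit requires both classes")
    X = sm.add_constant(tbr)
    try:
        res = sm.Logit(labels, X).fit(disp=0, maxiter=200)
        converged = bool(res.mle_retvals.get("converged", False))
        diagnostic = ""
    except Exception as exc:  # statsmodels raises on perfect separation
        return LogisticFit(
            intercept=float("nan"),
            slope=float("nan"),
            intercept_se=float("nan"),
            slope_se=float("nan"),
            intercept_p=float("nan"),
            slope_p=float("nan"),
            residual_deviance=float("nan"),
            converged=False,
            classification_threshold=None,
            diagnostic=f"fit failed: {exc}",
        )
    b0, b1 = (float(v) for v in res.params)
    # huge coefficients signal quasi-separation even when the optimiser
    # reports convergence
    if converged and max(abs(b0), abs(b1)) > 1e3:
        converged = False
        diagnostic = "coefficients diverged (separation suspected)"
    threshold = None
    if converged and abs(b1) > 1e-8:
        threshold = -b0 / b1
    prob = res.predict(X)
    accuracy = float(np.mean((prob > 0.5) == (labels > 0.5)))
    return LogisticFit(
        intercept=b0,
        slope=b1,
        intercept_se=float(res.bse[0]),
        slope_se=float(res.bse[1]),
        intercept_p=float(res.pvalues[0]),
        slope_p=float(res.pvalues[1]),
        residual_deviance=float(-2.0 * res.llf),
        converged=converged,
        classification_threshold=threshold,
        accuracy_in_sample=accuracy,
        diagnostic=diagnostic,
    )


def balanced_subsample(records: Sequence, seed: int = 0, label_key=None) -> list:
    """Down-sample the majority class to the minority count.

    ``records`` may be any sequence; labels are read from
    ``record.true_label`` unless ``label_key`` (a callable) is given.
    Selection is uniform without replacement, deterministic per seed;
    original record order is preserved.
    """
    if label_key is None:
        label_key = lambda r: bool(r.true_label)  # noqa: E731
    records = list(records)
    labels = np.array([label_key(r) for r in records], dtype=bool)
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ContractError("both classes must be present to balance")
    if n_pos == n_neg:
        return records
    rng = np.random.default_rng(seed)
    major = labels if n_pos > n_neg else ~labels
    keep_n = min(n_pos, n_neg)
    major_idx = np.flatnonzero(major)
    kept = set(rng.choice(major_idx, size=keep_n, replace=False).tolist())
    return [
        r
        for i, r in enumerate(records)
        if (not major[i]) or (i in kept)
    ]
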