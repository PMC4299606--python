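"""ROC / precision-recall machinery and model-comparison statistics.

AUC follows the Mann-Whitney convention (ties count 0.5); average precision
uses step interpolation over distinct score thresholds.  Paired classifiers
on the same samples are compared with DeLong's structural-component test for
AUC differences and a paired stratified bootstrap for TPR differences at a
fixed FPR.  Classification at a threshold predicts "case" for scores
strictly greater than the threshold.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ConfigurationError, ContractError

logger = logging.getLogger(__name__)


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    sidedness: str = "two-sided"

    def __post_init__(self) -> None:
        if not (0 <= self.p_value <= 1 or np.isnan(self.p_value)):
            raise ContractError(f"p-value {self.p_value} outside [0, 1]")


@dataclass
class ROCResult:
    """ROC points from (0,0) to (1,1), with AUC and optional TPR band."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    n_pos: int
    n_neg: int
    band_fpr: np.ndarray | None = None
    band_lo: np.ndarray | None = None
    band_hi: np.ndarray | None = None
    band_level: float | None = None


@dataclass
class ThresholdReport:
    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def tpr(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else np.nan

    @property
    def fpr(self) -> float:
        return self.fp / (self.fp + self.tn) if (self.fp + self.tn) else np.nan

    @property
    def specificity(self) -> float:
        return 1.0 - self.fpr


def _check_binary(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ContractError("scores and labels must be 1-D and aligned")
    if not set(np.unique(labels)) <= {0, 1}:
        raise ContractError("labels must be binary 0/1")
    return scores, labels


def mann_whitney_auc(scores, labels) -> float:
    """AUC as the normalized Mann-Whitney U statistic (ties count 0.5)."""
    scores, labels = _check_binary(scores, labels)
    n_pos, n_neg = int(labels.sum()), int((1 - labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ContractError("both classes must be present")
    ranks = stats.rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def roc_curve_points(scores, labels):
    """(fpr, tpr, thresholds) over all distinct thresholds, descending."""
    scores, labels = _check_binary(scores, labels)
    n_pos, n_neg = int(labels.sum()), len(labels) - int(labels.sum())
    order = np.argsort(-scores, kind="mergesort")
    s, y = scores[order], labels[order]
    distinct = np.r_[np.where(np.diff(s))[0], len(s) - 1]
    tp = np.cumsum(y)[distinct]
    fp = np.cumsum(1 - y)[distinct]
    fpr = np.r_[0.0, fp / n_neg]
    tpr = np.r_[0.0, tp / n_pos]
    thr = np.r_[np.inf, s[distinct]]
    return fpr, tpr, thr


def roc_auc(scores, labels) -> ROCResult:
    """ROC analysis: curve points plus Mann-Whitney AUC."""
    scores, labels = _check_binary(scores, labels)
    n_pos, n_neg = int(labels.sum()), len(labels) - int(labels.sum())
    if n_pos == 0 or n_neg == 0:
        raise ContractError("both classes must be present")
    fpr, tpr, thr = roc_curve_points(scores, labels)
    return ROCResult(
        fpr=fpr,
        tpr=tpr,
        thresholds=thr,
        auc=mann_whitney_auc(scores, labels),
        n_pos=n_pos,
        n_neg=n_neg,
    )


def auprc(scores, labels) -> float:
    """Average precision with step interpolation over distinct thresholds."""
    scores, labels = _check_binary(scores, labels)
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ContractError("auprc requires at least one case")
    order = np.argsort(-scores, kind="mergesort")
    s, y = scores[order], labels[order]
    distinct = np.r_[np.where(np.diff(s))[0], len(s) - 1]
    tp = np.cumsum(y)[distinct].astype(float)
    k = distinct + 1.0
    precision = tp / k
    recall = tp / n_pos
    drecall = np.diff(np.r_[0.0, recall])
    return float(np.sum(precision * drecall))


def tpr_at_fpr(scores, labels, fpr_target: float) -> float:
    """TPR at the most permissive threshold with empirical FPR <= target."""
    fpr, tpr, _ = roc_curve_points(scores, labels)
    ok = fpr <= fpr_target + 1e-12
    return float(tpr[ok].max())


def _stratified_boot_idx(labels, rng):
    pos = np.where(labels == 1)[0]
    neg = np.where(labels == 0)[0]
    return np.r_[rng.choice(pos, len(pos)), rng.choice(neg, len(neg))]


def tpr_ci_band(
    scores,
    labels,
    level: float = 0.95,
    n_boot: int = 2000,
    seed: int = 0,
    fpr_grid=None,
) -> ROCResult:
    """Stratified-bootstrap confidence band for TPR over an FPR grid.

    Cases and controls are resampled separately; the percentile interval at
    *level* is widened (anchored) to include the empirical curve point
    estimate at every grid point.  Deterministic given *seed*.
    """
    scores, labels = _check_binary(scores, labels)
    res = roc_auc(scores, labels)
    if res.n_pos < 5 or res.n_neg < 5:
        warnings.warn("fewer than 5 samples in a class; TPR band will be wide")
    if fpr_grid is None:
        fpr_grid = np.linspace(0.0, 1.0, 101)
    fpr_grid = np.asarray(fpr_grid, dtype=float)
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, len(fpr_grid)))
    for b in range(n_boot):
        idx = _stratified_boot_idx(labels, rng)
        f, t, _ = roc_curve_points(scores[idx], labels[idx])
        pos = np.searchsorted(f, fpr_grid + 1e-12, side="right") - 1
        boots[b] = t[pos]
    alpha = (1 - level) / 2
    lo = np.quantile(boots, alpha, axis=0)
    hi = np.quantile(boots, 1 - alpha, axis=0)
    pos = np.searchsorted(res.fpr, fpr_grid + 1e-12, side="right") - 1
    point = res.tpr[pos]
    res.band_fpr = fpr_grid
    res.band_lo = np.minimum(lo, point)
    res.band_hi = np.maximum(hi, point)
    res.band_level = level
    return res


def _delong_components(scores, labels):
    """Per-sample structural components (V10 for cases, V01 for controls)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    # midrank trick: psi(x_i, y_j) with 0.5 on ties, vectorized
    diff = pos[:, None] - neg[None, :]
    psi = (diff > 0).astype(float) + 0.5 * (diff == 0)
    return psi.mean(axis=1), 1.0 - psi.mean(axis=0), psi.mean()


def delong_test(scores_a, scores_b, labels, sidedness: str = "two-sided") -> TestResult:
    """DeLong test for the difference of two correlated AUCs.

    Both score vectors must be paired on the same samples.  ``sidedness``
    'one-sided-greater' tests AUC_a > AUC_b.
    """
    scores_a, labels = _check_binary(scores_a, labels)
    scores_b, labels_b = _check_binary(scores_b, labels)
    if len(scores_a) != len(scores_b):
        raise ContractError("paired scores must have identical length")
    v10_a, v01_a, auc_a = _delong_components(scores_a, labels)
    v10_b, v01_b, auc_b = _delong_components(scores_b, labels)
    m, n = len(v10_a), len(v01_a)
    if m < 2 or n < 2:
        raise ContractError("need >= 2 samples per class for DeLong variance")
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    # 1 - psi means V01 here is P(control outranks case); its variance for
    # the AUC is identical, covariances likewise.
    var = (
        (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    )
    delta = auc_a - auc_b
    if var <= 0:
        z = 0.0
        p = 1.0 if sidedness != "one-sided-less" else 1.0
    else:
        z = delta / np.sqrt(var)
        if sidedness == "two-sided":
            p = 2 * stats.norm.sf(abs(z))
        elif sidedness == "one-sided-greater":
            p = stats.norm.sf(z)
        elif sidedness == "one-sided-less":
            p = stats.norm.cdf(z)
        else:
            raise ConfigurationError(f"unknown sidedness {sidedness!r}")
    return TestResult(statistic=float(z), p_value=float(min(p, 1.0)), method="delong",
                      sidedness=sidedness)


def delong_variance(scores_a, scores_b, labels) -> float:
    """DeLong estimate of var(AUC_a - AUC_b) for paired scores."""
    scores_a, labels = _check_binary(scores_a, labels)
    scores_b, _ = _check_binary(scores_b, labels)
    v10_a, v01_a, _ = _delong_components(scores_a, labels)
    v10_b, v01_b, _ = _delong_components(scores_b, labels)
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    m, n = len(v10_a), len(v01_a)
    return float(
        (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    )


def bootstrap_tpr_test(
    scores_a,
    scores_b,
    labels,
    fpr_target: float,
    n_boot: int = 2000,
    seed: int = 0,
    sidedness: str = "one-sided-greater",
) -> TestResult:
    """Paired stratified bootstrap test of TPR difference at a fixed FPR.

    In each replicate both classifiers are evaluated on the same resampled
    cases and controls; TPR is taken at the most permissive threshold with
    empirical FPR <= *fpr_target*.  The one-sided (greater) p-value is the
    fraction of replicates where TPR_a - TPR_b <= 0.
    """
    scores_a, labels = _check_binary(scores_a, labels)
    scores_b, _ = _check_binary(scores_b, labels)
    if not (0 < fpr_target < 1):
        raise ConfigurationError("fpr_target must be in (0, 1)")
    if n_boot < 100:
        warnings.warn("n_boot < 100 gives a very coarse p-value")
    rng = np.random.default_rng(seed)
    diffs = np.empty(n_boot)
    for b in range(n_boot):
        idx = _stratified_boot_idx(labels, rng)
        ta = tpr_at_fpr(scores_a[idx], labels[idx], fpr_target)
        tb = tpr_at_fpr(scores_b[idx], labels[idx], fpr_target)
        diffs[b] = ta - tb
    observed = tpr_at_fpr(scores_a, labels, fpr_target) - tpr_at_fpr(
        scores_b, labels, fpr_target
    )
    p_greater = float(np.mean(diffs <= 0))
    if sidedness == "one-sided-greater":
        p = p_greater
    elif sidedness == "one-sided-less":
        p = float(np.mean(diffs >= 0))
    elif sidedness == "two-sided":
        p = min(1.0, 2 * min(p_greater, float(np.mean(diffs >= 0))))
    else:
        raise ConfigurationError(f"unknown sidedness {sidedness!r}")
    return TestResult(statistic=float(observed), p_value=p, method="bootstrap-tpr",
                      sidedness=sidedness)


def confusion_at_threshold(scores, labels, threshold: float) -> ThresholdReport:
    """Counts at a decision boundary: predict case iff score > threshold."""
    scores, labels = _check_binary(scores, labels)
    pred = scores > threshold
    return ThresholdReport(
        threshold=float(threshold),
        tp=int(np.sum(pred & (labels == 1))),
        fp=int(np.sum(pred & (labels == 0))),
        tn=int(np.sum(~pred & (labels == 0))),
        fn=int(np.sum(~pred & (labels == 1))),
    )


def choose_threshold(scores, labels, target_specificity: float):
    """Smallest threshold whose specificity meets *target_specificity*.

    Returns ``(threshold, achieved_specificity, achieved_sensitivity)``.
    An unattainable target falls back to the maximum score (everything
    predicted control) with a warning.
    """
    scores, labels = _check_binary(scores, labels)
    if not (0 <= target_specificity <= 1):
        raise ConfigurationError("target_specificity must be in [0, 1]")
    candidates = np.r_[scores.min() - 1.0, np.unique(scores)]
    for t in candidates:
        rep = confusion_at_threshold(scores, labels, t)
        if rep.specificity >= target_specificity:
            return float(t), rep.specificity, rep.tpr
    warnings.warn("target specificity unattainable; returning max-score threshold")
    rep = confusion_at_threshold(scores, labels, scores.max())
    return float(scores.max()), rep.specificity, rep.tpr


def error_rates_by_stratum(
    scores, labels, covariate, bins, threshold: float
) -> dict:
    """Confusion reports within covariate bins (age strata and the like).

    *bins* is either an integer (quantile bins) or explicit breakpoints.
    Empty bins are reported as ``None``.
    """
    scores, labels = _check_binary(scores, labels)
    covariate = np.asarray(covariate, dtype=float)
    if covariate.shape != scores.shape:
        raise ContractError("covariate must align with scores")
    if np.isnan(covariate).any():
        raise ContractError("covariate must be available for all samples")
    if np.isscalar(bins) or isinstance(bins, int):
        edges = np.quantile(covariate, np.linspace(0, 1, int(bins) + 1))
        edges = np.unique(edges)
    else:
        edges = np.asarray(bins, dtype=float)
    out = {}
    for i in range(len(edges) - 1):
        lo, hi = edges[i], edges[i + 1]
        if i == len(edges) - 2:
            sel = (covariate >= lo) & (covariate <= hi)
        else:
            sel = (covariate >= lo) & (covariate < hi)
        key = (float(lo), float(hi))
        if not sel.any():
            out[key] = None
            logger.info("error_rates_by_stratum: empty bin %s", key)
            continue
        out[key] = confusion_at_threshold(scores[sel], labels[sel], threshold)
    return out
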