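"""Univariate differential-abundance statistics and community descriptors.

Group comparisons use the Wilcoxon rank-sum test (exact permutation null for
small samples, normal approximation with tie correction otherwise) or its
Kruskal-Wallis generalization for more than two groups.  Multiple testing is
controlled with Benjamini-Hochberg FDR; fold change is the difference of
group-wise medians of log10-transformed abundances.  Two significance
rulesets are preset: taxonomic (adjusted p < 0.1, no fold-change criterion)
and functional (adjusted p < 0.01 and linear fold change > 1.33).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, ContractError, DataError, StageError
from .evaluation import TestResult
from .profiles import DEFAULT_PSEUDOCOUNT, FeatureMatrix

logger = logging.getLogger(__name__)

#: combined sample size at or below which the rank-sum null is enumerated
EXACT_MAX_N = 20


def _exact_ranksum_distribution(ranks2: np.ndarray, m: int):
    """Distribution of the group-1 rank sum under the permutation null.

    ``ranks2`` are the pooled midranks doubled (integers even with ties).
    Returns a dict {doubled rank sum: count} over all C(n, m) assignments,
    computed by dynamic programming over subset sums.
    """
    n = len(ranks2)
    # dp[k] maps achievable doubled-sum -> number of size-k subsets
    dp = [dict() for _ in range(m + 1)]
    dp[0][0] = 1
    for r in ranks2:
        for k in range(min(m, n) - 1, -1, -1):
            if not dp[k]:
                continue
            nxt = dp[k + 1]
            for s, c in dp[k].items():
                nxt[s + r] = nxt.get(s + r, 0) + c
    return dp[m]


def rank_test(groups: list, sidedness: str = "two-sided") -> TestResult:
    """Wilcoxon rank-sum (2 groups) or Kruskal-Wallis (> 2 groups).

    For two groups with combined n <= 20 the permutation null of the rank
    sum is enumerated exactly (midranks, so ties are handled); larger
    samples use the tie-corrected normal approximation.  One-sided
    alternatives refer to the first group's values being greater/less.
    """
    if len(groups) < 2:
        raise ContractError("rank_test requires >= 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ContractError("rank_test: empty group")
    if len(arrays) > 2:
        if sidedness != "two-sided":
            raise ConfigurationError("Kruskal-Wallis is two-sided only")
        if all(np.array_equal(arrays[0], a) for a in arrays[1:]) and len(
            set(map(len, arrays))
        ) == 1:
            # scipy raises on all-identical data; the null is trivially true
            return TestResult(0.0, 1.0, "kruskal-wallis", sidedness)
        try:
            stat, p = stats.kruskal(*arrays)
        except ValueError:
            return TestResult(0.0, 1.0, "kruskal-wallis", sidedness)
        return TestResult(float(stat), float(p), "kruskal-wallis", sidedness)

    x, y = arrays
    n1, n = len(x), len(x) + len(y)
    pooled = np.r_[x, y]
    ranks = stats.rankdata(pooled)
    w = float(ranks[:n1].sum())
    if n <= EXACT_MAX_N:
        ranks2 = np.rint(2 * ranks).astype(int)
        dist = _exact_ranksum_distribution(ranks2, n1)
        total = sum(dist.values())
        w2 = int(round(2 * w))
        mean2 = Fraction(n1 * (n + 1), 1)  # doubled mean = n1*(n+1)
        if sidedness == "two-sided":
            dev = abs(w2 - mean2)
            count = sum(c for s, c in dist.items() if abs(s - mean2) >= dev)
        elif sidedness == "one-sided-greater":
            count = sum(c for s, c in dist.items() if s >= w2)
        elif sidedness == "one-sided-less":
            count = sum(c for s, c in dist.items() if s <= w2)
        else:
            raise ConfigurationError(f"unknown sidedness {sidedness!r}")
        return TestResult(w, count / total, "wilcoxon-exact", sidedness)

    alt = {"two-sided": "two-sided", "one-sided-greater": "greater",
           "one-sided-less": "less"}.get(sidedness)
    if alt is None:
        raise ConfigurationError(f"unknown sidedness {sidedness!r}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stat, p = stats.mannwhitneyu(x, y, alternative=alt, method="asymptotic")
    if np.isnan(p):  # all values tied
        p = 1.0
    return TestResult(w, float(p), "wilcoxon-normal", sidedness)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise DataError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fold_change_log_median(x, y, x0: float) -> float:
    """median(log10(x + x0)) - median(log10(y + x0))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ContractError("fold change requires nonempty groups")
    return float(np.median(np.log10(x + x0)) - np.median(np.log10(y + x0)))


@dataclass(frozen=True)
class DiffAbundRuleset:
    """Significance ruleset: FDR level plus optional linear fold-change cutoff.

    ``min_abs_fold_change_linear = 1`` disables the fold-change criterion;
    a cutoff c > 1 requires |Delta log10 median| > log10(c).
    """

    alpha_adjusted: float
    min_abs_fold_change_linear: float = 1.0
    tag: str = "custom"

    def __post_init__(self) -> None:
        if not (0 < self.alpha_adjusted <= 1):
            raise ConfigurationError("alpha_adjusted must lie in (0, 1]")
        if self.min_abs_fold_change_linear < 1:
            raise ConfigurationError("min_abs_fold_change_linear must be >= 1")


TAXONOMIC_RULESET = DiffAbundRuleset(0.1, 1.0, tag="taxonomic")
FUNCTIONAL_RULESET = DiffAbundRuleset(0.01, 1.33, tag="functional")


def differential_abundance(
    matrix: FeatureMatrix,
    labels,
    ruleset: DiffAbundRuleset = TAXONOMIC_RULESET,
    x0: float | None = None,
) -> pd.DataFrame:
    """Per-feature rank test, BH adjustment, and log10-median fold change.

    *matrix* should already be low-abundance filtered (the filter precedes
    testing in the protocol).  *labels* align with the matrix samples
    (1 = case).  Returns a DataFrame with columns ``p``, ``p_adj``,
    ``fold_change_log10`` (case minus control medians) and ``significant``.
    """
    if matrix.stage != "raw":
        raise StageError("differential_abundance expects a raw abundance matrix")
    labels = np.asarray(labels, dtype=int)
    if labels.shape != (matrix.n_samples,):
        raise DataError("labels must align with matrix samples")
    if x0 is None:
        x0 = DEFAULT_PSEUDOCOUNT[matrix.feature_space]
    case = matrix.values[:, labels == 1]
    ctrl = matrix.values[:, labels == 0]
    if case.shape[1] == 0 or ctrl.shape[1] == 0:
        raise DataError("both groups must be nonempty")
    p = np.array([rank_test([case[i], ctrl[i]]).p_value for i in range(matrix.n_features)])
    p_adj = bh_adjust(p)
    fc = np.array(
        [fold_change_log_median(case[i], ctrl[i], x0) for i in range(matrix.n_features)]
    )
    # alpha = 1 and a fold-change cutoff of 1 each disable their criterion
    p_ok = p_adj < ruleset.alpha_adjusted if ruleset.alpha_adjusted < 1 else np.ones_like(p_adj, bool)
    if ruleset.min_abs_fold_change_linear > 1:
        fc_ok = np.abs(fc) > np.log10(ruleset.min_abs_fold_change_linear)
    else:
        fc_ok = np.ones_like(fc, bool)
    sig = p_ok & fc_ok
    return pd.DataFrame(
        {
            "p": p,
            "p_adj": p_adj,
            "fold_change_log10": fc,
            "significant": sig,
            "ruleset": ruleset.tag,
        },
        index=matrix.feature_ids,
    )


def fisher_exact(table) -> TestResult:
    """Two-sided Fisher exact test on a 2x2 contingency table."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise DataError("fisher_exact requires a 2x2 table")
    if (t < 0).any() or not np.issubdtype(t.dtype, np.integer) and not np.allclose(
        t, np.rint(t)
    ):
        raise DataError("counts must be nonnegative integers")
    t = np.rint(t).astype(int)
    if (t < 0).any():
        raise DataError("counts must be nonnegative integers")
    odds, p = stats.fisher_exact(t, alternative="two-sided")
    return TestResult(float(odds), float(p), "fisher-exact", "two-sided")


def diversity(matrix: FeatureMatrix) -> pd.DataFrame:
    """Per-sample Shannon index H (natural log) and species richness S.

    H is computed over each sample's nonzero abundances renormalized to sum
    to one; an all-zero sample gets missing H with a warning.
    """
    if matrix.stage != "raw":
        raise StageError("diversity expects a raw abundance matrix")
    H = np.full(matrix.n_samples, np.nan)
    S = (matrix.values > 0).sum(axis=0)
    for j in range(matrix.n_samples):
        v = matrix.values[:, j]
        v = v[v > 0]
        if v.size == 0:
            warnings.warn(f"sample {matrix.sample_ids[j]!r} is all-zero; H undefined")
            continue
        p = v / v.sum()
        H[j] = float(-(p * np.log(p)).sum())
    return pd.DataFrame({"shannon": H, "richness": S}, index=matrix.sample_ids)


def phylum_ratio(
    matrix: FeatureMatrix, numerator: str, denominator: str
) -> pd.Series:
    """Per-sample summed-abundance ratio of two phyla (e.g. Bacteroidetes:Firmicutes).

    Requires feature metadata with a ``phylum`` column, or a ``lineage``
    column of semicolon-separated ranks containing ``p__<Phylum>``.  A
    sample with zero denominator-phylum abundance gets a missing value.
    """
    if matrix.feature_meta is None:
        raise DataError("phylum_ratio requires feature lineage metadata")
    meta = matrix.feature_meta
    if "phylum" in meta.columns:
        phyla = meta["phylum"].astype(str)
    elif "lineage" in meta.columns:
        def _extract(lineage: str) -> str:
            for part in str(lineage).split(";"):
                part = part.strip()
                if part.startswith("p__"):
                    return part[3:]
            return ""
        phyla = meta["lineage"].map(_extract)
    else:
        raise DataError("feature metadata needs a 'phylum' or 'lineage' column")
    phyla = phyla.reindex(matrix.feature_ids).astype(str)
    vocab = set(phyla.dropna())
    for name in (numerator, denominator):
        if name not in vocab:
            raise DataError(f"phylum {name!r} absent from feature metadata")
    num = matrix.values[(phyla == numerator).to_numpy()].sum(axis=0)
    den = matrix.values[(phyla == denominator).to_numpy()].sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(den > 0, num / den, np.nan)
    return pd.Series(ratio, index=matrix.sample_ids)
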