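"""Consensus marker signatures and ordination / progression statistics.

The consensus signature summarizes an ensemble of sparse linear models:
each feature's *support* is the fraction of models giving it a nonzero
coefficient, its weight share is the mean percentage of each model's total
absolute coefficient weight, and its direction follows the sign of the mean
coefficient (positive log-odds = case-enriched).  Features with support of
at least 50% of the models form the signature, ordered by mean weight
share.

Progression analysis embeds log-abundances of disease-associated features
with PCA and correlates the first component with four ordered clinical
groups (no neoplasia, adenoma, early CRC, late CRC).  Classical metric
scaling (PCoA) of a sample-distance matrix provides the community-structure
coordinates for the ordination baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .errors import ContractError, DataError
from .diffabund import rank_test
from .evaluation import TestResult
from .lasso import ModelEnsemble
from .profiles import FeatureMatrix, SampleMetadata

logger = logging.getLogger(__name__)


@dataclass
class ConsensusSignature:
    """Per-feature ensemble summary; ``table`` holds the selected signature."""

    table: pd.DataFrame  # support, mean_percent_weight, mean_coefficient, direction
    all_features: pd.DataFrame
    n_models: int
    n_zero_models: int
    min_support: float


def extract_consensus(ensemble: ModelEnsemble, min_support: float = 0.5) -> ConsensusSignature:
    """Consensus marker extraction from the ensemble coefficients.

    Per model, a feature's percentage is ``100 |w_f| / sum_g |w_g|``;
    all-zero models contribute no percentages (they are excluded from the
    percentage mean and logged) but count as zero support.  The signature
    keeps features with support >= *min_support* (inclusive), ordered by
    mean percentage descending.  Mean signed coefficients average over all
    models, zeros included, matching the mean log-odds bars of an ensemble
    coefficient plot.
    """
    if not ensemble.models:
        raise ContractError("ensemble is empty")
    fids = ensemble.models[0][2].feature_ids
    W = np.vstack([m.weights for _, _, m in ensemble.models])  # models x features
    n_models = W.shape[0]
    absW = np.abs(W)
    totals = absW.sum(axis=1)
    nonzero_models = totals > 0
    n_zero = int((~nonzero_models).sum())
    if n_zero:
        logger.warning("extract_consensus: %d all-zero model(s) excluded from "
                       "percentage averaging", n_zero)
    support = (W != 0).mean(axis=0)
    pct = np.zeros(W.shape[1])
    if nonzero_models.any():
        shares = 100.0 * absW[nonzero_models] / totals[nonzero_models, None]
        pct = shares.mean(axis=0)
    mean_coef = W.mean(axis=0)
    direction = np.where(mean_coef >= 0, "case-enriched", "control-enriched")
    full = pd.DataFrame(
        {
            "support": support,
            "mean_percent_weight": pct,
            "mean_coefficient": mean_coef,
            "direction": direction,
        },
        index=pd.Index(fids, name="feature"),
    ).sort_values("mean_percent_weight", ascending=False)
    selected = full[full["support"] >= min_support]
    return ConsensusSignature(
        table=selected.copy(),
        all_features=full,
        n_models=n_models,
        n_zero_models=n_zero,
        min_support=min_support,
    )


#: ordinal progression groups: diagnosis group -> stage 1..4
_STAGE_MAP = {
    "neoplasia-free": 1,
    "small-adenoma": 2,
    "large-adenoma": 2,
    "crc-0": 3,
    "crc-I": 3,
    "crc-II": 3,
    "crc-III": 4,
    "crc-IV": 4,
}


def stage_grouping(metadata: SampleMetadata) -> pd.Series:
    """Ordered progression groups: 1 no neoplasia, 2 adenoma (any size),
    3 CRC AJCC 0-II, 4 CRC AJCC III-IV.  IBD/unknown groups are excluded
    (dropped with a logged count)."""
    groups = metadata.table["diagnosis_group"].map(_STAGE_MAP)
    n_excl = int(groups.isna().sum())
    if n_excl:
        logger.info("stage_grouping: excluded %d sample(s) outside the progression axis",
                    n_excl)
    return groups.dropna().astype(int)


@dataclass
class ProgressionResult:
    coordinates: pd.DataFrame  # samples x components
    variance_fractions: np.ndarray
    loadings: pd.DataFrame | None = None
    spearman: TestResult | None = None
    pairwise_p: pd.DataFrame | None = None


def pca_embed(matrix: FeatureMatrix, feature_subset=None) -> ProgressionResult:
    """Centered (unscaled) PCA of a log-stage matrix, optionally on a subset.

    Sign convention: each component's largest-magnitude loading is positive,
    so embeddings are deterministic.
    """
    if matrix.stage != "log":
        raise ContractError("pca_embed expects a log-stage matrix")
    if feature_subset is not None:
        subset = list(feature_subset)
        if not subset:
            raise ContractError("feature subset must be nonempty")
        matrix = matrix.select_features(subset)
    if matrix.n_samples < 3:
        raise ContractError("pca_embed requires >= 3 samples")
    X = matrix.values.T  # samples x features
    Xc = X - X.mean(axis=0)
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    # fix signs: largest |loading| positive per component
    for i in range(vt.shape[0]):
        j = int(np.argmax(np.abs(vt[i])))
        if vt[i, j] < 0:
            vt[i] *= -1
            u[:, i] *= -1
    coords = u * s
    var = s**2
    frac = var / var.sum() if var.sum() > 0 else var
    comp_names = [f"PC{i+1}" for i in range(len(s))]
    return ProgressionResult(
        coordinates=pd.DataFrame(coords, index=matrix.sample_ids, columns=comp_names),
        variance_fractions=frac,
        loadings=pd.DataFrame(vt.T, index=matrix.feature_ids, columns=comp_names),
    )


def progression_correlation(pc1, groups) -> tuple[TestResult, pd.DataFrame]:
    """Spearman correlation of PC1 with ordinal stage plus pairwise rank tests.

    Pairwise two-group Wilcoxon p-values are reported unadjusted, mirroring
    the typical per-pair annotation of progression plots.
    """
    pc1 = pd.Series(np.asarray(pc1, dtype=float),
                    index=groups.index if hasattr(groups, "index") else None)
    groups = pd.Series(groups)
    levels = sorted(groups.unique())
    if len(levels) < 2:
        raise ContractError("need >= 2 distinct groups")
    if np.allclose(pc1, pc1.iloc[0]):
        logger.warning("progression_correlation: constant PC1, rho undefined")
        sp = TestResult(np.nan, np.nan, "spearman", "two-sided")
    else:
        rho, p = stats.spearmanr(pc1, groups)
        sp = TestResult(float(rho), float(p), "spearman", "two-sided")
    mat = pd.DataFrame(np.nan, index=levels, columns=levels)
    for i, a in enumerate(levels):
        for b in levels[i + 1:]:
            res = rank_test([pc1[groups == a].to_numpy(), pc1[groups == b].to_numpy()])
            mat.loc[a, b] = mat.loc[b, a] = res.p_value
    return sp, mat


def bray_curtis(matrix: FeatureMatrix) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarities between samples (raw abundances)."""
    if matrix.stage != "raw":
        raise ContractError("bray_curtis expects a raw abundance matrix")
    D = squareform(pdist(matrix.values.T, metric="braycurtis"))
    return pd.DataFrame(D, index=matrix.sample_ids, columns=matrix.sample_ids)


def pcoa_embed(distance, n_components: int = 10) -> ProgressionResult:
    """Classical metric scaling of a symmetric zero-diagonal distance matrix.

    Double-centers the squared distances and eigendecomposes; negative
    eigenvalues (non-Euclidean input) are dropped with their total
    magnitude logged.  Returns coordinates for up to *n_components*
    positive-eigenvalue axes and eigenvalue fractions over the positive
    spectrum.
    """
    if isinstance(distance, pd.DataFrame):
        ids = np.asarray(distance.index, dtype=object)
        D = distance.to_numpy(dtype=float)
    else:
        D = np.asarray(distance, dtype=float)
        ids = np.arange(D.shape[0])
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise DataError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise DataError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0, atol=1e-10):
        raise DataError("distance matrix must have a zero diagonal")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(1e-12, 1e-10 * abs(evals).max() if evals.size else 0)
    neg_mag = float(-evals[evals < 0].sum())
    if neg_mag > 1e-10:
        logger.info("pcoa_embed: dropped negative eigenvalues with total magnitude %.3g",
                    neg_mag)
    evals_p, evecs_p = evals[pos], evecs[:, pos]
    k = min(n_components, len(evals_p))
    coords = evecs_p[:, :k] * np.sqrt(evals_p[:k])
    for i in range(coords.shape[1]):
        j = int(np.argmax(np.abs(coords[:, i])))
        if coords[j, i] < 0:
            coords[:, i] *= -1
    frac = evals_p / evals_p.sum() if evals_p.size else evals_p
    names = [f"PCo{i+1}" for i in range(k)]
    return ProgressionResult(
        coordinates=pd.DataFrame(coords, index=ids, columns=names),
        variance_fractions=frac[:k] if k else frac,
    )
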