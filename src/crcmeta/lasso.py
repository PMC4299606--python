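"""Resampled nested-CV LASSO ensemble for case-control classification.

The seven-step protocol: (1) unsupervised low-abundance filtering, (2) log
transform and standardization with smoothed standard deviations, (3)
ten-times-resampled stratified 10-fold cross-validation, (4) per-fold L1
(LASSO) logistic regression with the penalty tuned in a nested 5-fold CV by
area under the precision-recall curve, enforcing at least five nonzero
coefficients and weighting controls five times as heavily as cases, (5)
test-fold predictions averaged per sample over repetitions, (6) ROC
analysis of the mean prediction scores, and (7) consensus marker extraction
from the ensemble coefficients (see :mod:`crcmeta.signatures`).

External validation applies the frozen normalization state and every model
in the ensemble to an independent cohort, averaging the scores.

The L1 fits use LIBLINEAR (via scikit-learn); ``lambda`` is defined as the
reciprocal of LIBLINEAR's C, i.e. the objective is
``||w||_1 + (1/lambda) * sum_i c_i * logloss_i`` with per-class weights c.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .errors import ConfigurationError, ContractError, DataError
from .evaluation import auprc
from .profiles import (
    FeatureMatrix,
    NormalizationState,
    SampleMetadata,
    apply_normalization,
    derive_binary_labels,
    filter_low_abundance,
    log_transform,
    standardize,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Protocol parameters; the defaults are the study protocol.

    ``normalization`` selects whether filtering/standardization are fitted
    once on the full cross-validation population before partitioning
    (``global``, the protocol default) or refitted inside each training
    fold (``within-fold``, which is leakage-free but departs from the
    stated step order).
    """

    k_outer: int = 10
    n_repeats: int = 10
    k_inner: int = 5
    lambda_grid: tuple[float, ...] | None = None  # None -> data-adaptive grid
    n_lambda: int = 20
    min_nonzero: int = 5
    control_case_weight: float = 5.0
    seed: int = 0
    normalization: str = "global"
    filter_threshold: float | None = None
    pseudocount: float | None = None
    meta_fields: tuple[str, ...] = ()
    label_task: str = "crc"

    def __post_init__(self) -> None:
        if self.k_outer < 2:
            raise ConfigurationError("k_outer must be >= 2")
        if self.k_inner < 2:
            raise ConfigurationError("k_inner must be >= 2")
        if self.n_repeats < 1:
            raise ConfigurationError("n_repeats must be >= 1")
        if self.min_nonzero < 1:
            raise ConfigurationError("min_nonzero must be >= 1")
        if self.control_case_weight <= 0:
            raise ConfigurationError("control_case_weight must be > 0")
        if self.normalization not in ("global", "within-fold"):
            raise ConfigurationError("normalization must be 'global' or 'within-fold'")
        if self.lambda_grid is not None and len(self.lambda_grid) == 0:
            raise ConfigurationError("lambda_grid must be nonempty")


@dataclass
class CVPlan:
    """Resampled stratified partitions: folds[r][k] = (train_ids, test_ids)."""

    folds: list  # list over repetitions of list of (train_ids, test_ids)
    seed: int

    @property
    def n_repeats(self) -> int:
        return len(self.folds)

    @property
    def k_outer(self) -> int:
        return len(self.folds[0]) if self.folds else 0


@dataclass
class LinearModel:
    """One sparse linear model: weights are log-odds per standardized unit."""

    feature_ids: np.ndarray
    weights: np.ndarray
    intercept: float
    lam: float
    control_case_weight: float
    tuning: pd.DataFrame | None = None  # per-candidate lambda, auprc, nnz
    fallback: bool = False

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.weights))

    def decision(self, X: np.ndarray) -> np.ndarray:
        return X @ self.weights + self.intercept

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.decision(X)))


@dataclass
class ModelEnsemble:
    """The r x k trained models with their CV plan and aggregated scores."""

    models: list  # list of (repetition, fold, LinearModel)
    norm_state: NormalizationState
    plan: CVPlan
    config: PipelineConfig
    sample_ids: np.ndarray
    labels: np.ndarray
    score_matrix: np.ndarray  # samples x repetitions, test-fold predictions
    cv_scores: np.ndarray  # per-sample mean over repetitions

    @property
    def n_models(self) -> int:
        return len(self.models)


@dataclass
class PredictionSet:
    sample_ids: np.ndarray
    mean_scores: np.ndarray
    source: str  # "cv" or "external"
    per_model_scores: np.ndarray | None = None  # samples x models


def _seed_int(*parts) -> int:
    return int(np.random.SeedSequence(tuple(int(p) for p in parts)).generate_state(1)[0] % (2**31))


def make_cv_plan(labels: pd.Series, config: PipelineConfig) -> CVPlan:
    """n_repeats independent stratified k_outer-fold partitions of the samples."""
    y = np.asarray(labels, dtype=int)
    ids = np.asarray(labels.index, dtype=object)
    for cls in (0, 1):
        if (y == cls).sum() < config.k_outer:
            raise ContractError(
                f"class {cls} has {(y == cls).sum()} samples < k_outer={config.k_outer}; "
                "use a smaller k_outer"
            )
    folds = []
    for r in range(config.n_repeats):
        skf = StratifiedKFold(
            n_splits=config.k_outer, shuffle=True, random_state=_seed_int(config.seed, r)
        )
        rep = [
            (ids[tr].copy(), ids[te].copy())
            for tr, te in skf.split(np.zeros(len(y)), y)
        ]
        folds.append(rep)
    return CVPlan(folds=folds, seed=config.seed)


def default_lambda_grid(X: np.ndarray, y: np.ndarray, control_weight: float,
                        n_lambda: int = 20) -> np.ndarray:
    """Geometric penalty grid from lambda_max (all-zero solution) downward.

    ``lambda_max`` is the largest absolute weighted score-gradient at the
    null model, the glmnet convention for the smallest penalty that still
    zeroes every coefficient; the grid spans three decades below it.
    """
    c = np.where(y == 0, control_weight, 1.0)
    p0 = np.average(y, weights=c)
    grad = X.T @ (c * (y - p0))
    lam_max = float(np.abs(grad).max())
    if lam_max <= 0:
        lam_max = 1.0
    return np.geomspace(lam_max, lam_max * 1e-3, n_lambda)


def fit_lasso(
    X: np.ndarray, y: np.ndarray, lam: float, control_case_weight: float,
    feature_ids=None,
) -> LinearModel:
    """Weighted L1-penalized logistic regression (LIBLINEAR backend).

    *X* is samples x features (standardized); controls get
    ``control_case_weight`` times the per-example weight of cases.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if not np.isfinite(X).all():
        raise DataError("non-finite values in the feature matrix")
    if len(set(y)) < 2:
        raise ContractError("both classes must be present")
    clf = LogisticRegression(
        l1_ratio=1.0,
        solver="liblinear",
        C=1.0 / lam,
        class_weight={0: control_case_weight, 1: 1.0},
        random_state=0,
        max_iter=200,
        tol=1e-5,
    )
    clf.fit(X, y)
    if feature_ids is None:
        feature_ids = np.arange(X.shape[1])
    return LinearModel(
        feature_ids=np.asarray(feature_ids, dtype=object),
        weights=clf.coef_.ravel().copy(),
        intercept=float(clf.intercept_[0]),
        lam=float(lam),
        control_case_weight=control_case_weight,
    )


def tune_lambda(
    X: np.ndarray, y: np.ndarray, config: PipelineConfig, seed: int,
    feature_ids=None,
) -> LinearModel:
    """Nested-CV penalty selection by AUPRC, then refit on the full subset.

    For each candidate penalty, k_inner-fold stratified CV inside the
    training subset yields pooled inner-test predictions scored by average
    precision.  Candidates are then tried in descending score order and the
    first whose full-training refit keeps at least ``min_nonzero`` nonzero
    coefficients wins; if none qualifies the least-penalized candidate is
    used and flagged as a fallback.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    grid = (
        np.asarray(config.lambda_grid, dtype=float)
        if config.lambda_grid is not None
        else default_lambda_grid(X, y, config.control_case_weight, config.n_lambda)
    )
    if grid.size == 0:
        raise ConfigurationError("lambda_grid must be nonempty")
    k = min(config.k_inner, int((y == 0).sum()), int((y == 1).sum()))
    if k < 2:
        raise ContractError("too few samples per class for inner CV")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2**31))
    splits = list(skf.split(X, y))
    scores = np.empty(grid.size)
    for gi, lam in enumerate(grid):
        pooled = np.empty(len(y))
        for tr, te in splits:
            m = fit_lasso(X[tr], y[tr], lam, config.control_case_weight)
            pooled[te] = m.predict_proba(X[te])
        scores[gi] = auprc(pooled, y)
    order = np.argsort(-scores, kind="stable")  # ties -> stronger penalty first
    record = []
    chosen = None
    for gi in order:
        m = fit_lasso(X, y, grid[gi], config.control_case_weight,
                      feature_ids=feature_ids)
        record.append({"lambda": grid[gi], "auprc": scores[gi], "nnz": m.n_nonzero})
        if m.n_nonzero >= config.min_nonzero:
            chosen = m
            break
    if chosen is None:
        gi = int(np.argmin(grid))
        chosen = fit_lasso(X, y, grid[gi], config.control_case_weight,
                           feature_ids=feature_ids)
        chosen.fallback = True
        logger.warning(
            "tune_lambda: no candidate reached %d nonzero coefficients; "
            "falling back to the least-penalized lambda=%g (nnz=%d)",
            config.min_nonzero, grid[gi], chosen.n_nonzero,
        )
    chosen.tuning = pd.DataFrame(
        {"lambda": grid, "auprc": scores}
    ).assign(refit_nnz=[dict((r["lambda"], r["nnz"]) for r in record).get(l, np.nan)
                        for l in grid])
    return chosen


def encode_meta_features(metadata: SampleMetadata, fields: Sequence[str],
                         sample_ids) -> tuple[pd.DataFrame, list]:
    """Numeric encodings of metadata covariates for use as extra predictors.

    FOBT and gender become 0/1; age and BMI stay in natural units (years,
    kg/m^2); standardization happens downstream together with the abundance
    features.  Samples missing any requested field are dropped (count
    logged).  Returns (fields x samples frame, kept sample ids).
    """
    known = {"fobt", "gender", "age", "bmi"}
    bad = set(fields) - known
    if bad:
        raise ConfigurationError(f"unknown metadata field(s): {sorted(bad)}")
    tab = metadata.table.loc[list(sample_ids)]
    enc = {}
    for f in fields:
        if f == "fobt":
            enc["meta_fobt"] = tab["fobt"].map({"positive": 1.0, "negative": 0.0})
        elif f == "gender":
            enc["meta_gender"] = tab["gender"].map({"M": 1.0, "F": 0.0})
        else:
            enc[f"meta_{f}"] = pd.to_numeric(tab[f], errors="coerce")
    frame = pd.DataFrame(enc, index=tab.index).T
    keep = frame.columns[frame.notna().all(axis=0)]
    dropped = len(frame.columns) - len(keep)
    if dropped:
        logger.info("encode_meta_features: dropped %d sample(s) missing %s",
                    dropped, list(fields))
    return frame[keep], list(keep)


def augment_with_meta(
    matrix: FeatureMatrix, metadata: SampleMetadata, fields: Sequence[str]
) -> FeatureMatrix:
    """Append encoded metadata rows to a log-stage feature matrix.

    The appended rows are tagged ``category='meta'`` in the feature
    metadata so the normalization state can distinguish them from
    abundances.  Samples missing a requested field are dropped.
    """
    if matrix.stage != "log":
        raise ContractError("augment_with_meta expects a log-stage matrix "
                            "(filter and log-transform abundances first)")
    frame, keep = encode_meta_features(metadata, fields, matrix.sample_ids)
    sub = matrix.select_samples(keep)
    new_ids = np.r_[sub.feature_ids, np.asarray(frame.index, dtype=object)]
    new_vals = np.vstack([sub.values, frame.to_numpy(dtype=float)])
    meta_df = (
        sub.feature_meta.copy()
        if sub.feature_meta is not None
        else pd.DataFrame(index=pd.Index(sub.feature_ids))
    )
    if "category" not in meta_df.columns:
        meta_df["category"] = "abundance"
    add = pd.DataFrame({"category": "meta"}, index=pd.Index(frame.index))
    meta_df = pd.concat([meta_df, add])
    return replace(
        sub,
        feature_ids=new_ids,
        values=new_vals,
        feature_meta=meta_df,
        feature_space="mixed",
    )


def build_meta_matrix(metadata: SampleMetadata, fields: Sequence[str],
                      sample_ids=None) -> FeatureMatrix:
    """A metadata-only predictor matrix (the confounder-baseline design)."""
    ids = metadata.sample_ids if sample_ids is None else sample_ids
    frame, keep = encode_meta_features(metadata, fields, ids)
    return FeatureMatrix(
        feature_ids=np.asarray(frame.index, dtype=object),
        sample_ids=np.asarray(keep, dtype=object),
        values=frame.to_numpy(dtype=float),
        stage="log",  # numeric predictors ready for standardization
        feature_space="meta",
        feature_meta=pd.DataFrame({"category": "meta"}, index=pd.Index(frame.index)),
    )


def _prepare_standardized(matrix, metadata, config):
    """filter -> log -> (augment) -> standardize on the given samples."""
    filtered, _ = filter_low_abundance(matrix, config.filter_threshold)
    logged = log_transform(filtered, config.pseudocount)
    if config.meta_fields:
        logged = augment_with_meta(logged, metadata, config.meta_fields)
    return standardize(logged)


def run_cv_ensemble(
    matrix: FeatureMatrix, metadata: SampleMetadata, config: PipelineConfig
) -> ModelEnsemble:
    """Execute the full resampled nested-CV protocol on a raw cohort."""
    labels, included = derive_binary_labels(metadata, config.label_task)
    sub = matrix.select_samples(list(included))
    if config.meta_fields:
        # samples missing a requested meta field leave the labeled set
        _, keep = encode_meta_features(metadata, config.meta_fields, included)
        labels = labels.loc[keep]
        sub = matrix.select_samples(keep)
    if config.normalization == "global":
        std, state = _prepare_standardized(sub, metadata, config)
    else:
        # state still fitted globally for external use; per-fold states are
        # refitted inside the loop below
        std, state = _prepare_standardized(sub, metadata, config)
    y_all = labels.loc[list(std.sample_ids)]
    plan = make_cv_plan(y_all, config)
    ids = np.asarray(y_all.index, dtype=object)
    pos = {s: i for i, s in enumerate(ids)}
    X_all = std.values.T  # samples x features
    y_arr = np.asarray(y_all, dtype=int)

    n = len(ids)
    score_matrix = np.full((n, config.n_repeats), np.nan)
    models = []
    for r, rep in enumerate(plan.folds):
        for k, (train_ids, test_ids) in enumerate(rep):
            tr = np.array([pos[s] for s in train_ids])
            te = np.array([pos[s] for s in test_ids])
            if config.normalization == "within-fold":
                fold_raw = sub.select_samples(list(train_ids))
                fold_std, fold_state = _prepare_standardized(fold_raw, metadata, config)
                Xtr = fold_std.values.T
                test_raw = sub.select_samples(list(test_ids))
                test_std = _apply_state(test_raw, metadata, fold_state, config.meta_fields)
                Xte = test_std.values.T
                fids = fold_std.feature_ids
            else:
                Xtr, Xte = X_all[tr], X_all[te]
                fids = std.feature_ids
            model = tune_lambda(
                Xtr, y_arr[tr], config, seed=_seed_int(config.seed, r, k),
                feature_ids=fids,
            )
            score_matrix[te, r] = model.predict_proba(Xte)
            models.append((r, k, model))
    if np.isnan(score_matrix).any():
        raise ContractError("internal: some samples received no test prediction")
    return ModelEnsemble(
        models=models,
        norm_state=state,
        plan=plan,
        config=config,
        sample_ids=ids,
        labels=y_arr,
        score_matrix=score_matrix,
        cv_scores=score_matrix.mean(axis=1),
    )


def _apply_state(matrix, metadata, state, meta_fields):
    """Frozen normalization for matrices that may need meta rows appended."""
    if not len(state.meta_feature_ids):
        return apply_normalization(matrix, state)
    abundance_ids = [f for f in state.feature_ids if f not in set(state.meta_feature_ids)]
    have = set(matrix.feature_ids)
    missing = [f for f in abundance_ids if f not in have]
    if missing:
        from .errors import FeatureMismatchError

        raise FeatureMismatchError(missing)
    sub = matrix.select_features(abundance_ids)
    logged = replace(sub, values=np.log10(sub.values + state.x0), stage="log",
                     x0=state.x0)
    fields = [str(f).removeprefix("meta_") for f in state.meta_feature_ids]
    mixed = augment_with_meta(logged, metadata, fields)
    mixed = mixed.select_features(list(state.feature_ids))
    vals = (mixed.values - state.centers[:, None]) / state.scales[:, None]
    return replace(mixed, values=vals, stage="standardized")


def external_validate(
    ensemble: ModelEnsemble,
    matrix: FeatureMatrix,
    metadata: SampleMetadata | None = None,
) -> PredictionSet:
    """Score an independent cohort with every model in the ensemble.

    Applies the frozen normalization state, then all r x k models; the
    returned mean score per sample averages every model's prediction.
    *metadata* is only needed when the ensemble uses metadata covariates.
    """
    cfg = ensemble.config
    if cfg.meta_fields and metadata is None:
        raise ContractError("ensemble uses metadata fields; metadata required")
    if cfg.meta_fields:
        std = _apply_state(matrix, metadata, ensemble.norm_state, cfg.meta_fields)
    else:
        std = apply_normalization(matrix, ensemble.norm_state)
    X = std.values.T
    per_model = np.column_stack([m.predict_proba(X) for _, _, m in ensemble.models])
    return PredictionSet(
        sample_ids=std.sample_ids.copy(),
        mean_scores=per_model.mean(axis=1),
        source="external",
        per_model_scores=per_model,
    )


def train_baseline_logistic(
    matrix: FeatureMatrix,
    labels: pd.Series,
    k: int = 10,
    n_repeats: int = 1,
    seed: int = 0,
) -> PredictionSet:
    """Unpenalized logistic regression in the same resampled-CV harness.

    Used for the patient-metadata confounder baseline (gender, age, BMI)
    and the community-structure baseline (principal coordinates plus the
    Bacteroidetes:Firmicutes ratio).  Expects few (<= ~15) predictors.
    """
    if matrix.n_features > 15:
        raise ContractError("baseline logistic expects <= 15 predictors")
    y = np.asarray(labels.loc[list(matrix.sample_ids)], dtype=int)
    X = matrix.values.T
    # center/scale for optimizer stability; an affine map leaves the
    # unpenalized fit's predictions unchanged
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd
    n = len(y)
    scores = np.full((n, n_repeats), np.nan)
    for r in range(n_repeats):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=_seed_int(seed, r))
        for tr, te in skf.split(Xs, y):
            clf = LogisticRegression(C=1e8, solver="lbfgs", max_iter=2000)
            clf.fit(Xs[tr], y[tr])
            scores[te, r] = clf.predict_proba(Xs[te])[:, 1]
    return PredictionSet(
        sample_ids=matrix.sample_ids.copy(),
        mean_scores=scores.mean(axis=1),
        source="cv",
        per_model_scores=scores,
    )
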