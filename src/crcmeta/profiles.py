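"""Abundance data model: feature matrices, metadata, normalization.

The central objects are :class:`FeatureMatrix` (features x samples relative
abundances with a processing-stage tag), :class:`SampleMetadata` (diagnosis
groups and covariates) and :class:`NormalizationState` (the frozen filter
mask, pseudocount, per-feature centers and smoothed scales that make external
validation reproducible).

Processing order is fixed: low-abundance filtering on raw relative
abundances, then ``log10(x + x0)`` transformation, then standardization with
smoothed standard deviations.  External cohorts are normalized with the
frozen state, never re-estimated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    ContractError,
    DataError,
    FeatureMismatchError,
    StageError,
)

logger = logging.getLogger(__name__)

STAGES = ("raw", "log", "standardized")

FEATURE_SPACES = (
    "taxonomic-species",
    "taxonomic-genus",
    "taxonomic-phylum",
    "functional-kegg",
    "functional-cazy",
    "meta",
    "mixed",
)

#: Default low-abundance filter threshold per feature space: a feature is
#: dropped when its relative abundance never exceeds this value in any sample.
DEFAULT_FILTER_THRESHOLD = {
    "taxonomic-species": 1e-3,
    "taxonomic-genus": 1e-3,
    "taxonomic-phylum": 1e-3,
    "functional-kegg": 1e-4,
    "functional-cazy": 1e-4,
    "meta": 0.0,
    "mixed": 1e-4,
}

#: Default pseudocount for the log10 transform per feature space.
DEFAULT_PSEUDOCOUNT = {
    "taxonomic-species": 1e-6,
    "taxonomic-genus": 1e-6,
    "taxonomic-phylum": 1e-6,
    "functional-kegg": 1e-8,
    "functional-cazy": 1e-8,
    "meta": 1e-6,
    "mixed": 1e-6,
}

DIAGNOSIS_GROUPS = (
    "neoplasia-free",
    "small-adenoma",
    "large-adenoma",
    "crc-0",
    "crc-I",
    "crc-II",
    "crc-III",
    "crc-IV",
    "ibd-uc",
    "ibd-cd",
    "unknown-control",
)

CRC_GROUPS = ("crc-0", "crc-I", "crc-II", "crc-III", "crc-IV")


@dataclass
class FeatureMatrix:
    """Features x samples abundance table with a processing-stage tag.

    Parameters
    ----------
    feature_ids, sample_ids
        Unique string identifiers for rows and columns.
    values
        2-D float array, shape ``(n_features, n_samples)``.
    stage
        One of ``raw`` (relative abundances in [0, 1], column sums <= 1),
        ``log`` (log10 of pseudocounted abundances) or ``standardized``.
    feature_space
        Which feature vocabulary the rows come from (taxonomic, functional,
        metadata covariates, or mixed).
    feature_meta
        Optional per-feature table indexed by feature id (e.g. ``lineage``
        for taxa or ``category`` for functional/meta features).
    x0
        Pseudocount used by the log transform; recorded on log-stage
        matrices so downstream standardization can freeze it.
    """

    feature_ids: np.ndarray
    sample_ids: np.ndarray
    values: np.ndarray
    stage: str = "raw"
    feature_space: str = "taxonomic-species"
    feature_meta: pd.DataFrame | None = None
    x0: float | None = None

    def __post_init__(self) -> None:
        self.feature_ids = np.asarray(self.feature_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        if self.stage not in STAGES:
            raise StageError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if self.feature_space not in FEATURE_SPACES:
            raise DataError(
                f"unknown feature_space {self.feature_space!r}; expected one of {FEATURE_SPACES}"
            )
        if self.values.ndim != 2:
            raise DataError("values must be a 2-D array (features x samples)")
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise DataError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        for name, ids in (("feature", self.feature_ids), ("sample", self.sample_ids)):
            if len(set(ids)) != len(ids):
                dup = pd.Index(ids)[pd.Index(ids).duplicated()][0]
                raise DataError(f"duplicate {name} id: {dup!r}")
        if self.stage == "raw":
            if self.values.size and self.values.min() < 0:
                raise DataError("raw abundances must be nonnegative")
            colsums = self.values.sum(axis=0)
            if colsums.size and colsums.max() > 1 + 1e-6:
                bad = self.sample_ids[int(np.argmax(colsums))]
                raise DataError(
                    f"raw column sums must be <= 1 (sample {bad!r} sums to {colsums.max():.6g})"
                )

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)

    def select_samples(self, sample_ids: Sequence) -> "FeatureMatrix":
        idx = pd.Index(self.sample_ids)
        pos = idx.get_indexer(list(sample_ids))
        if (pos < 0).any():
            missing = [s for s, p in zip(sample_ids, pos) if p < 0]
            raise DataError(f"unknown sample ids: {missing[:5]}")
        return replace(
            self,
            sample_ids=np.asarray(list(sample_ids), dtype=object),
            values=self.values[:, pos],
        )

    def select_features(self, feature_ids: Sequence) -> "FeatureMatrix":
        idx = pd.Index(self.feature_ids)
        pos = idx.get_indexer(list(feature_ids))
        if (pos < 0).any():
            missing = [f for f, p in zip(feature_ids, pos) if p < 0]
            raise FeatureMismatchError(missing)
        meta = None
        if self.feature_meta is not None:
            meta = self.feature_meta.reindex(list(feature_ids))
        return replace(
            self,
            feature_ids=np.asarray(list(feature_ids), dtype=object),
            values=self.values[pos, :],
            feature_meta=meta,
        )

    def copy(self) -> "FeatureMatrix":
        return replace(
            self,
            feature_ids=self.feature_ids.copy(),
            sample_ids=self.sample_ids.copy(),
            values=self.values.copy(),
            feature_meta=None if self.feature_meta is None else self.feature_meta.copy(),
        )


METADATA_COLUMNS = (
    "sample_id",
    "diagnosis_group",
    "cohort",
    "age",
    "gender",
    "bmi",
    "fobt",
)

FOBT_VALUES = ("positive", "negative")
GENDER_VALUES = ("F", "M")


@dataclass
class SampleMetadata:
    """Validated per-sample metadata table.

    Wraps a DataFrame indexed by ``sample_id`` with columns
    ``diagnosis_group`` (mandatory, from the fixed vocabulary), ``cohort``,
    ``age`` (years), ``gender`` (F/M), ``bmi`` (kg/m^2) and ``fobt``
    (positive/negative); all but the diagnosis group may be missing (NaN).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        if "sample_id" in df.columns:
            df = df.set_index("sample_id")
        df = df.copy()
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()][0]
            raise DataError(f"duplicate sample id: {dup!r}")
        if "diagnosis_group" not in df.columns:
            raise DataError("metadata requires a diagnosis_group column")
        bad = set(df["diagnosis_group"].dropna()) - set(DIAGNOSIS_GROUPS)
        if bad:
            raise DataError(f"unknown diagnosis_group value(s): {sorted(bad)}")
        if df["diagnosis_group"].isna().any():
            raise DataError("diagnosis_group must not be missing")
        if "age" in df.columns:
            ages = pd.to_numeric(df["age"], errors="coerce")
            if (ages.dropna() <= 0).any():
                raise DataError("age must be positive when present")
            df["age"] = ages
        if "fobt" in df.columns:
            bad = set(df["fobt"].dropna()) - set(FOBT_VALUES)
            if bad:
                raise DataError(f"unknown fobt value(s): {sorted(bad)}")
        for col in METADATA_COLUMNS[1:]:
            if col not in df.columns:
                df[col] = np.nan
        self.table = df

    @property
    def sample_ids(self) -> np.ndarray:
        return np.asarray(self.table.index, dtype=object)

    def __len__(self) -> int:
        return len(self.table)

    def subset(self, sample_ids: Sequence) -> "SampleMetadata":
        missing = set(sample_ids) - set(self.table.index)
        if missing:
            raise DataError(f"unknown sample ids: {sorted(missing)[:5]}")
        return SampleMetadata(self.table.loc[list(sample_ids)].copy())


@dataclass
class NormalizationState:
    """Frozen normalization parameters fitted on a training population.

    Applying the state is a pure function: the retained-feature mask,
    pseudocount ``x0``, per-feature centers ``mu`` and smoothed scales
    ``sigma + q10`` are used exactly as frozen, never re-estimated.  ``q10``
    is the 10th percentile (linear interpolation) of the raw per-feature
    standard deviations of the fitting set.
    """

    feature_ids: np.ndarray  # retained features, in order
    x0: float
    centers: np.ndarray
    scales: np.ndarray  # smoothed: sigma_f + q10
    sigma: np.ndarray  # raw per-feature standard deviations
    q10: float
    fit_sample_ids: np.ndarray = field(default_factory=lambda: np.array([], dtype=object))
    #: feature ids of the pre-filter matrix that were dropped (audit trail)
    dropped_feature_ids: np.ndarray = field(default_factory=lambda: np.array([], dtype=object))
    #: rows that are encoded metadata covariates rather than abundances
    meta_feature_ids: np.ndarray = field(default_factory=lambda: np.array([], dtype=object))

    def __post_init__(self) -> None:
        self.feature_ids = np.asarray(self.feature_ids, dtype=object)
        self.centers = np.asarray(self.centers, dtype=float)
        self.scales = np.asarray(self.scales, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        n = len(self.feature_ids)
        if not (len(self.centers) == len(self.scales) == len(self.sigma) == n):
            raise DataError("normalization state arrays must align with feature_ids")
        if self.x0 <= 0:
            raise ConfigurationError("x0 must be > 0")
        if n and (self.sigma > 0).any() and (self.scales <= 0).any():
            raise DataError("smoothed scales must be strictly positive")


def filter_low_abundance(
    matrix: FeatureMatrix, threshold: float | None = None
) -> tuple[FeatureMatrix, np.ndarray]:
    """Drop features whose maximum relative abundance never exceeds *threshold*.

    The rule is strict: a feature survives only if ``max_s x_fs > threshold``.
    Default thresholds are 1e-3 for taxonomic and 1e-4 for functional or
    mixed feature spaces.  Returns the filtered matrix and the boolean
    retained-feature mask (aligned to the input features).
    """
    if matrix.stage != "raw":
        raise StageError(f"filter_low_abundance requires stage=raw, got {matrix.stage!r}")
    if threshold is None:
        threshold = DEFAULT_FILTER_THRESHOLD[matrix.feature_space]
    if threshold < 0:
        raise ConfigurationError("threshold must be >= 0")
    mask = matrix.values.max(axis=1) > threshold if matrix.n_samples else np.ones(
        matrix.n_features, bool
    )
    out = matrix.select_features(list(matrix.feature_ids[mask]))
    return out, mask


def log_transform(matrix: FeatureMatrix, x0: float | None = None) -> FeatureMatrix:
    """Return ``log10(x + x0)`` of a raw matrix.

    Default pseudocounts: 1e-6 for taxonomic, 1e-8 for functional features.
    """
    if matrix.stage != "raw":
        raise StageError(f"log_transform requires stage=raw, got {matrix.stage!r}")
    if x0 is None:
        x0 = DEFAULT_PSEUDOCOUNT[matrix.feature_space]
    if x0 <= 0:
        raise ConfigurationError("x0 must be > 0")
    out = matrix.copy()
    out.values = np.log10(matrix.values + x0)
    out.stage = "log"
    out.x0 = float(x0)
    return out


def standardize(matrix: FeatureMatrix) -> tuple[FeatureMatrix, NormalizationState]:
    """Center each feature to mean 0 and divide by its smoothed scale.

    The smoothed scale is ``sigma_f + q10`` where ``sigma_f`` is the
    feature's standard deviation (ddof=1, the R convention) and ``q10`` the
    10th percentile of all per-feature standard deviations; the smoothing
    keeps near-constant features from exploding.  Requires a log-stage
    matrix with at least two samples.
    """
    if matrix.stage != "log":
        raise StageError(f"standardize requires stage=log, got {matrix.stage!r}")
    if matrix.n_samples < 2:
        raise ContractError("standardize requires >= 2 samples (no variance on one)")
    centers = matrix.values.mean(axis=1)
    sigma = matrix.values.std(axis=1, ddof=1)
    q10 = float(np.percentile(sigma, 10)) if matrix.n_features else 0.0
    scales = sigma + q10
    if matrix.n_features and (scales <= 0).all():
        raise ContractError("all features constant; nothing to standardize")
    out = matrix.copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        out.values = (matrix.values - centers[:, None]) / scales[:, None]
    out.values = np.nan_to_num(out.values, nan=0.0, posinf=0.0, neginf=0.0)
    out.stage = "standardized"
    meta_ids = np.array([], dtype=object)
    if matrix.feature_meta is not None and "category" in matrix.feature_meta.columns:
        is_meta = matrix.feature_meta["category"].astype(str) == "meta"
        meta_ids = np.asarray(matrix.feature_meta.index[is_meta], dtype=object)
    state = NormalizationState(
        feature_ids=matrix.feature_ids.copy(),
        x0=matrix.x0 if matrix.x0 is not None else DEFAULT_PSEUDOCOUNT[matrix.feature_space],
        centers=centers,
        scales=scales,
        sigma=sigma,
        q10=q10,
        fit_sample_ids=matrix.sample_ids.copy(),
        meta_feature_ids=meta_ids,
    )
    return out, state


def apply_normalization(matrix: FeatureMatrix, state: NormalizationState) -> FeatureMatrix:
    """Apply a frozen :class:`NormalizationState` to a raw abundance matrix.

    Subsets to the retained features (extra features are dropped; a missing
    retained feature is an error listing the ids), applies the frozen
    pseudocount log transform, then the frozen centers and smoothed scales.
    Metadata-covariate rows recorded in the state are not expected in a raw
    abundance matrix and must be appended by the caller before this step via
    the pipeline (see :func:`crcmeta.lasso.external_validate`).
    """
    if matrix.stage != "raw":
        raise StageError(f"apply_normalization requires stage=raw, got {matrix.stage!r}")
    abundance_ids = [f for f in state.feature_ids if f not in set(state.meta_feature_ids)]
    have = set(matrix.feature_ids)
    missing = [f for f in abundance_ids if f not in have]
    if missing:
        raise FeatureMismatchError(missing)
    sub = matrix.select_features(abundance_ids)
    logged = np.log10(sub.values + state.x0)
    idx = pd.Index(state.feature_ids)
    pos = idx.get_indexer(abundance_ids)
    out = replace(
        sub,
        values=(logged - state.centers[pos, None]) / state.scales[pos, None],
        stage="standardized",
        x0=state.x0,
    )
    return out


def fit_normalization(
    matrix: FeatureMatrix,
    threshold: float | None = None,
    x0: float | None = None,
) -> tuple[FeatureMatrix, NormalizationState]:
    """Convenience chain: filter -> log -> standardize, with full audit trail."""
    filtered, mask = filter_low_abundance(matrix, threshold)
    logged = log_transform(filtered, x0)
    std, state = standardize(logged)
    state.dropped_feature_ids = np.asarray(matrix.feature_ids[~mask], dtype=object)
    return std, state


LABEL_TASKS = {
    # case groups, control groups; everything else is excluded from labeling
    "crc": (
        set(CRC_GROUPS),
        {"neoplasia-free", "small-adenoma", "unknown-control"},
    ),
    # all-neoplasia task: adenomas of any size count as cases
    "neoplasia": (
        set(CRC_GROUPS) | {"small-adenoma", "large-adenoma"},
        {"neoplasia-free", "unknown-control"},
    ),
}


def derive_binary_labels(
    metadata: SampleMetadata, task: str = "crc"
) -> tuple[pd.Series, np.ndarray]:
    """Binary labels (1 = case) for a classification task.

    The default ``crc`` task labels all CRC stages as cases and
    neoplasia-free participants plus small-adenoma (< 10 mm) patients as
    controls; large adenomas and IBD groups are excluded from the labeled
    set (they can still be scored at prediction time).

    Returns the label Series (indexed by sample id) and the included ids.
    """
    if task not in LABEL_TASKS:
        raise ConfigurationError(f"unknown label task {task!r}; options: {sorted(LABEL_TASKS)}")
    cases, controls = LABEL_TASKS[task]
    groups = metadata.table["diagnosis_group"]
    labels = pd.Series(
        np.where(groups.isin(cases), 1, np.where(groups.isin(controls), 0, -1)),
        index=metadata.table.index,
    )
    included = labels.index[labels >= 0]
    n_excl = int((labels < 0).sum())
    if n_excl:
        logger.info("derive_binary_labels: excluded %d sample(s) from the labeled set", n_excl)
    return labels.loc[included], np.asarray(included, dtype=object)


def prevalence(matrix: FeatureMatrix, floor: float = 1e-5) -> pd.Series:
    """Fraction of samples in which each feature exceeds *floor* (strictly)."""
    if matrix.stage != "raw":
        raise StageError(f"prevalence requires stage=raw, got {matrix.stage!r}")
    if floor < 0:
        raise ConfigurationError("floor must be >= 0")
    frac = (matrix.values > floor).mean(axis=1)
    return pd.Series(frac, index=matrix.feature_ids)
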