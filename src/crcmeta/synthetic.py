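"""Synthetic case-control microbiome cohorts with known ground truth.

The generator emulates the structure of shotgun-metagenomic species
profiles: heavy-tailed log10-normal base abundances, per-feature Bernoulli
presence (zero inflation), per-sample renormalization to ``1 - unmapped
fraction`` (compositional closure with an explicit unmapped remainder),
planted marker features whose case-group location is shifted on the log10
scale, optional per-cohort batch shifts for external-validation scenarios,
an age covariate confounded with case status, and an imperfect binary
screening test of the fecal-occult-blood type.

Because the generative model is fully known, every cohort carries its true
per-sample log-odds score, whose empirical AUC is the oracle ceiling any
classifier can be compared against.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ContractError
from .evaluation import mann_whitney_auc
from .profiles import FeatureMatrix, SampleMetadata

# named substreams of the global seed; the index keeps streams independent
# so toggling one component does not perturb the others
_STREAMS = {"features": 0, "presence": 1, "abundance": 2, "unmapped": 3,
            "covariates": 4, "fobt": 5, "batch": 6}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, _STREAMS[stream])))


@dataclass(frozen=True)
class Marker(object):
    """A planted marker: feature index, direction, and log10 fold change."""

    index: int
    direction: Literal["enriched", "depleted"]
    effect: float  # |Delta| of the case-group log10 location

    @property
    def signed_effect(self) -> float:
        return self.effect if self.direction == "enriched" else -self.effect


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic cohort.

    Base per-feature log10-abundance locations are drawn uniformly from
    ``location_range`` and scales from ``scale_range``; ``prevalence`` is
    the per-feature presence probability (scalar or per-feature array).
    Marker features draw their base location from the narrower
    ``marker_location_range`` (default 1e-4 to 1e-3 relative abundance):
    disease-associated species are modeled as moderately abundant, so the
    planted signal survives detection floors and low-abundance filtering,
    and so compositional closure does not let a single shifted feature
    dominate the community (which would leak class signal into every other
    feature and blur the planted truth).  Marker features are present with
    probability ``marker_prevalence`` (default 1): the planted signal is a
    pure location shift of consistently-detected species, so the true
    generative log-odds stays within the linear-in-log-abundance family
    that the downstream classifier fits; background features keep the
    configured zero inflation.
    ``batch_shift`` is the standard deviation of a per-feature location
    offset applied to the whole cohort (0 = no batch effect).  Cases' ages
    are shifted by ``age_shift_years`` to mimic the age confounding typical
    of CRC case-control studies.
    """

    n_cases: int
    n_controls: int
    n_features: int
    markers: tuple[Marker, ...] = ()
    location_range: tuple[float, float] = (-6.0, -2.0)
    marker_location_range: tuple[float, float] = (-3.8, -3.0)
    scale_range: tuple[float, float] = (0.4, 1.0)
    prevalence: float | Sequence[float] = 0.9
    marker_prevalence: float = 1.0
    unmapped_fraction_range: tuple[float, float] = (0.1, 0.4)
    batch_shift: float = 0.0
    fobt_sensitivity: float = 0.30
    fobt_specificity: float = 0.95
    age_shift_years: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cases", "n_controls", "n_features"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        idxs = [m.index for m in self.markers]
        if len(set(idxs)) != len(idxs):
            raise ConfigurationError("markers: feature indices must be unique")
        for m in self.markers:
            if not (0 <= m.index < self.n_features):
                raise ConfigurationError(f"markers: index {m.index} out of range")
            if m.direction not in ("enriched", "depleted"):
                raise ConfigurationError(f"markers: unknown direction {m.direction!r}")
            if not np.isfinite(m.effect):
                raise ConfigurationError("markers: effect must be finite")
        prev = np.atleast_1d(np.asarray(self.prevalence, dtype=float))
        if ((prev < 0) | (prev > 1)).any():
            raise ConfigurationError("prevalence must lie in [0, 1]")
        if not (0 <= self.marker_prevalence <= 1):
            raise ConfigurationError("marker_prevalence must lie in [0, 1]")
        if prev.size not in (1, self.n_features):
            raise ConfigurationError("prevalence must be scalar or length n_features")
        lo, hi = self.unmapped_fraction_range
        if not (0 <= lo <= hi < 1):
            raise ConfigurationError("unmapped_fraction_range must satisfy 0 <= lo <= hi < 1")
        for name in ("fobt_sensitivity", "fobt_specificity"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.batch_shift < 0:
            raise ConfigurationError("batch_shift must be >= 0")

    @property
    def n_samples(self) -> int:
        return self.n_cases + self.n_controls

    def prevalence_vector(self) -> np.ndarray:
        prev = np.atleast_1d(np.asarray(self.prevalence, dtype=float))
        out = (
            np.broadcast_to(prev, (self.n_features,)).copy()
            if prev.size == 1
            else prev.copy()
        )
        for m in self.markers:
            out[m.index] = self.marker_prevalence
        return out


@dataclass
class SyntheticCohort:
    """A generated cohort: abundances, metadata, and its generative truth."""

    matrix: FeatureMatrix
    metadata: SampleMetadata
    truth: tuple[Marker, ...]
    log_odds: np.ndarray  # per-sample true generative log-odds of case
    oracle_auc_estimate: float
    config: GeneratorConfig
    labels: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


# case diagnosis groups roughly follow the stage mix of a screening-clinic
# CRC series; controls split between neoplasia-free and small adenomas
_CASE_STAGE_P = {"crc-0": 0.05, "crc-I": 0.25, "crc-II": 0.15, "crc-III": 0.20, "crc-IV": 0.35}
_CONTROL_GROUP_P = {"neoplasia-free": 0.7, "small-adenoma": 0.3}


def simulate_fobt(labels, sensitivity: float, specificity: float, seed: int = 0) -> np.ndarray:
    """Imperfect binary screen: P(+|case)=sensitivity, P(+|control)=1-specificity."""
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        raise ContractError("labels must be nonempty")
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity)):
        if not (0 <= v <= 1):
            raise ConfigurationError(f"{name} must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    u = rng.random(labels.size)
    p_pos = np.where(labels == 1, sensitivity, 1.0 - specificity)
    return (u < p_pos).astype(int)


def generate_cohort(config: GeneratorConfig, cohort_id: str = "sim") -> SyntheticCohort:
    """Generate one cohort under *config*; bit-identical for equal config+seed."""
    n_f, n_s = config.n_features, config.n_samples
    labels = np.r_[np.ones(config.n_cases, dtype=int), np.zeros(config.n_controls, dtype=int)]

    rng_feat = _rng(config.seed, "features")
    loc = rng_feat.uniform(*config.location_range, size=n_f)
    scale = rng_feat.uniform(*config.scale_range, size=n_f)
    for m in config.markers:  # markers sit in the moderate-abundance band
        loc[m.index] = rng_feat.uniform(*config.marker_location_range)
    prev = config.prevalence_vector()

    shift = np.zeros(n_f)
    for m in config.markers:
        shift[m.index] = m.signed_effect

    batch = np.zeros(n_f)
    if config.batch_shift > 0:
        batch = _rng(config.seed, "batch").normal(0.0, config.batch_shift, size=n_f)

    z = _rng(config.seed, "abundance").standard_normal((n_f, n_s))
    latent = loc[:, None] + batch[:, None] + scale[:, None] * z
    latent = latent + shift[:, None] * labels[None, :]

    present = _rng(config.seed, "presence").random((n_f, n_s)) < prev[:, None]
    values = np.where(present, 10.0 ** latent, 0.0)

    unmapped = _rng(config.seed, "unmapped").uniform(*config.unmapped_fraction_range, size=n_s)
    colsum = values.sum(axis=0)
    target = 1.0 - unmapped
    nonzero = colsum > 0
    values[:, nonzero] *= target[nonzero] / colsum[nonzero]

    # true log-odds from the latent (pre-closure) marker values: presence is
    # class-independent, so absent markers contribute nothing
    log_odds = np.zeros(n_s)
    for m in config.markers:
        i, d = m.index, m.signed_effect
        mu0 = loc[i] + batch[i]
        x = latent[i]
        contrib = ((x - mu0) ** 2 - (x - mu0 - d) ** 2) / (2.0 * scale[i] ** 2)
        log_odds += np.where(present[i], contrib, 0.0)

    rng_cov = _rng(config.seed, "covariates")
    age = rng_cov.normal(62.0, 10.0, size=n_s) + config.age_shift_years * labels
    age = np.clip(age, 20.0, 95.0)
    gender = np.where(rng_cov.random(n_s) < 0.5, "F", "M")
    bmi = np.clip(rng_cov.normal(26.0, 4.0, size=n_s), 15.0, 50.0)
    groups = np.empty(n_s, dtype=object)
    case_groups, case_p = zip(*_CASE_STAGE_P.items())
    ctrl_groups, ctrl_p = zip(*_CONTROL_GROUP_P.items())
    groups[labels == 1] = rng_cov.choice(case_groups, size=config.n_cases, p=case_p)
    groups[labels == 0] = rng_cov.choice(ctrl_groups, size=config.n_controls, p=ctrl_p)

    fobt = simulate_fobt(
        labels, config.fobt_sensitivity, config.fobt_specificity,
        seed=np.random.SeedSequence((config.seed, _STREAMS["fobt"])).generate_state(1)[0] % (2**31),
    )

    sample_ids = np.array([f"{cohort_id}-s{j:04d}" for j in range(n_s)], dtype=object)
    feature_ids = np.array([f"sp{i:04d}" for i in range(n_f)], dtype=object)
    matrix = FeatureMatrix(
        feature_ids=feature_ids,
        sample_ids=sample_ids,
        values=values,
        stage="raw",
        feature_space="taxonomic-species",
    )
    meta = SampleMetadata(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "diagnosis_group": groups,
                "cohort": cohort_id,
                "age": np.round(age, 1),
                "gender": gender,
                "bmi": np.round(bmi, 1),
                "fobt": np.where(fobt == 1, "positive", "negative"),
            }
        )
    )
    if labels.sum() and (1 - labels).sum():
        oracle = mann_whitney_auc(log_odds, labels)
    else:
        oracle = 0.5
    return SyntheticCohort(
        matrix=matrix,
        metadata=meta,
        truth=tuple(config.markers),
        log_odds=log_odds,
        oracle_auc_estimate=float(oracle),
        config=config,
        labels=labels,
    )


def oracle_auc(cohort: SyntheticCohort, n_mc: int = 1, seed: int = 0) -> float:
    """Empirical AUC of the true generative log-odds against labels.

    With ``n_mc > 1``, averages the log-odds AUC over *n_mc* freshly
    generated cohorts from the same configuration (Monte-Carlo estimate of
    the oracle ceiling); otherwise scores the cohort itself.
    """
    if cohort.log_odds is None or len(cohort.log_odds) == 0:
        raise ContractError("cohort carries no generative log-odds")
    if n_mc <= 1:
        return float(mann_whitney_auc(cohort.log_odds, cohort.labels))
    aucs = []
    base = np.random.SeedSequence((seed, 97)).generate_state(n_mc) % (2**31)
    for s in base:
        c = generate_cohort(replace(cohort.config, seed=int(s)))
        aucs.append(mann_whitney_auc(c.log_odds, c.labels))
    return float(np.mean(aucs))
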