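"""Shared fixtures: small synthetic cohorts and a trained ensemble.

Session-scoped fixtures keep the expensive nested-CV runs to one per
session; tests that need different conditions build their own cohorts.
"""

import numpy as np
import pandas as pd
import pytest

from crcmeta.lasso import PipelineConfig, run_cv_ensemble
from crcmeta.profiles import FeatureMatrix, SampleMetadata
from crcmeta.synthetic import GeneratorConfig, Marker, generate_cohort


def strong_markers(n: int = 10, spacing: int = 30) -> tuple:
    """n planted markers with |Delta log10| = 1, alternating direction."""
    return tuple(
        Marker(i * spacing, "enriched" if i % 2 == 0 else "depleted", 1.0)
        for i in range(n)
    )


@pytest.fixture(scope="session")
def strong_cohort():
    """Strong-signal study conditions: 300 features, 10 planted markers."""
    cfg = GeneratorConfig(
        n_cases=75, n_controls=75, n_features=300, markers=strong_markers(), seed=11
    )
    return generate_cohort(cfg, cohort_id="train")


@pytest.fixture(scope="session")
def small_cohort():
    """A fast cohort for bookkeeping tests (not for accuracy claims)."""
    cfg = GeneratorConfig(
        n_cases=30, n_controls=30, n_features=80, markers=strong_markers(6, 12),
        seed=7,
    )
    return generate_cohort(cfg, cohort_id="small")


@pytest.fixture(scope="session")
def small_config():
    return PipelineConfig(k_outer=5, n_repeats=2, k_inner=3, n_lambda=8, seed=7)


@pytest.fixture(scope="session")
def small_ensemble(small_cohort, small_config):
    return run_cv_ensemble(small_cohort.matrix, small_cohort.metadata, small_config)


@pytest.fixture()
def tiny_raw_matrix():
    """A hand-sized raw matrix with known values."""
    vals = np.array(
        [
            [0.30, 0.10, 0.20],
            [0.0005, 0.0002, 0.0004],
            [0.00005, 0.00002, 0.00004],
            [0.10, 0.40, 0.30],
        ]
    )
    return FeatureMatrix(
        feature_ids=np.array(["a", "b", "c", "d"], dtype=object),
        sample_ids=np.array(["s1", "s2", "s3"], dtype=object),
        values=vals,
    )


def make_metadata(groups, cohort="X", **extra):
    n = len(groups)
    base = {
        "sample_id": [f"{cohort}-{i}" for i in range(n)],
        "diagnosis_group": list(groups),
        "cohort": cohort,
        "age": 60.0,
        "gender": "F",
        "bmi": 25.0,
        "fobt": "negative",
    }
    base.update(extra)
    return SampleMetadata(pd.DataFrame(base))
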