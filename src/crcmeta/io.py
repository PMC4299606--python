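"""On-disk formats: profile/metadata TSV dialects and the ensemble JSON document.

Profiles are features-as-rows TSV (the common metagenomic convention),
UTF-8, with ``#``-prefixed header comments carrying the processing stage
and feature-space tags.  Metadata is a plain TSV with ``NA`` as the missing
token.  A trained ensemble round-trips through a single JSON document with
full-precision weights, so reloaded models predict bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import asdict

import numpy as np
import pandas as pd

from . import __version__
from .errors import IntegrityError, ParseError
from .lasso import CVPlan, LinearModel, ModelEnsemble, PipelineConfig
from .profiles import (
    FEATURE_SPACES,
    FeatureMatrix,
    NormalizationState,
    SampleMetadata,
    STAGES,
)

ENSEMBLE_FORMAT_VERSION = 1
_NA = "NA"


def write_profile(matrix: FeatureMatrix, path) -> None:
    """Write a FeatureMatrix as tagged TSV (lossless full-precision floats)."""
    with open(path, "w") as fh:
        fh.write(f"# stage={matrix.stage}\n")
        fh.write(f"# feature_space={matrix.feature_space}\n")
        if matrix.x0 is not None:
            fh.write(f"# x0={matrix.x0!r}\n")
        fh.write("feature_id\t" + "\t".join(map(str, matrix.sample_ids)) + "\n")
        for fid, row in zip(matrix.feature_ids, matrix.values):
            fh.write(str(fid) + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_profile(path, feature_meta: pd.DataFrame | None = None) -> FeatureMatrix:
    """Parse a profile TSV written by :func:`write_profile` (or by hand)."""
    stage, space, x0 = "raw", "taxonomic-species", None
    header = None
    feature_ids, rows = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    key, val = key.strip(), val.strip()
                    if key == "stage":
                        if val not in STAGES:
                            raise ParseError(f"line {lineno}: unknown stage {val!r}")
                        stage = val
                    elif key == "feature_space":
                        if val not in FEATURE_SPACES:
                            raise ParseError(f"line {lineno}: unknown feature_space {val!r}")
                        space = val
                    elif key == "x0":
                        x0 = float(val)
                continue
            parts = line.split("\t")
            if header is None:
                header = parts[1:]
                if len(set(header)) != len(header):
                    dup = pd.Index(header)[pd.Index(header).duplicated()][0]
                    raise ParseError(f"line {lineno}: duplicate sample id {dup!r}")
                continue
            if len(parts) != len(header) + 1:
                raise ParseError(
                    f"line {lineno}: expected {len(header) + 1} columns, got {len(parts)}"
                )
            fid = parts[0]
            if fid in set(feature_ids):
                raise ParseError(f"line {lineno}: duplicate feature id {fid!r}")
            try:
                rows.append([float(v) for v in parts[1:]])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: non-numeric cell ({exc})") from exc
            feature_ids.append(fid)
    if header is None:
        raise ParseError("no header row found")
    return FeatureMatrix(
        feature_ids=np.asarray(feature_ids, dtype=object),
        sample_ids=np.asarray(header, dtype=object),
        values=np.asarray(rows, dtype=float) if rows else np.empty((0, len(header))),
        stage=stage,
        feature_space=space,
        feature_meta=feature_meta,
        x0=x0,
    )


def write_metadata(metadata: SampleMetadata, path) -> None:
    df = metadata.table.reset_index()
    cols = ["sample_id" if c == "index" else c for c in df.columns]
    df.columns = cols
    df.to_csv(path, sep="\t", index=False, na_rep=_NA)


def read_metadata(path) -> SampleMetadata:
    try:
        df = pd.read_csv(path, sep="\t", dtype={"sample_id": str},
                         na_values=[_NA], keep_default_na=False)
    except Exception as exc:
        raise ParseError(f"could not parse metadata table: {exc}") from exc
    if "sample_id" not in df.columns:
        raise ParseError("metadata table needs a sample_id column")
    return SampleMetadata(df)


def read_lineage(path) -> pd.DataFrame:
    """Sidecar lineage TSV: feature_id, rank, lineage."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("feature_id", "lineage"):
        if col not in df.columns:
            raise ParseError(f"lineage table needs a {col!r} column")
    return df.set_index("feature_id")


def _state_to_doc(state: NormalizationState) -> dict:
    return {
        "feature_ids": list(map(str, state.feature_ids)),
        "x0": state.x0,
        "centers": state.centers.tolist(),
        "scales": state.scales.tolist(),
        "sigma": state.sigma.tolist(),
        "q10": state.q10,
        "fit_sample_ids": list(map(str, state.fit_sample_ids)),
        "dropped_feature_ids": list(map(str, state.dropped_feature_ids)),
        "meta_feature_ids": list(map(str, state.meta_feature_ids)),
    }


def _state_from_doc(doc: dict) -> NormalizationState:
    return NormalizationState(
        feature_ids=np.asarray(doc["feature_ids"], dtype=object),
        x0=doc["x0"],
        centers=np.asarray(doc["centers"], dtype=float),
        scales=np.asarray(doc["scales"], dtype=float),
        sigma=np.asarray(doc["sigma"], dtype=float),
        q10=doc["q10"],
        fit_sample_ids=np.asarray(doc["fit_sample_ids"], dtype=object),
        dropped_feature_ids=np.asarray(doc["dropped_feature_ids"], dtype=object),
        meta_feature_ids=np.asarray(doc["meta_feature_ids"], dtype=object),
    )


def save_ensemble(ensemble: ModelEnsemble, path) -> None:
    """Serialize an ensemble (models, state, plan, scores, config) to JSON."""
    models_doc = []
    for r, k, m in ensemble.models:
        nz = np.nonzero(m.weights)[0]
        models_doc.append(
            {
                "repetition": r,
                "fold": k,
                "lambda": m.lam,
                "intercept": m.intercept,
                "weights": {str(m.feature_ids[i]): float(m.weights[i]) for i in nz},
                "fallback": m.fallback,
                "tuning": None if m.tuning is None else m.tuning.to_dict("list"),
            }
        )
    doc = {
        "format_version": ENSEMBLE_FORMAT_VERSION,
        "software_version": __version__,
        "config": asdict(ensemble.config),
        "normalization": _state_to_doc(ensemble.norm_state),
        "plan": {
            "seed": ensemble.plan.seed,
            "folds": [
                [[list(map(str, tr)), list(map(str, te))] for tr, te in rep]
                for rep in ensemble.plan.folds
            ],
        },
        "model_feature_ids": list(map(str, ensemble.models[0][2].feature_ids)),
        "models": models_doc,
        "sample_ids": list(map(str, ensemble.sample_ids)),
        "labels": ensemble.labels.tolist(),
        "score_matrix": ensemble.score_matrix.tolist(),
        "cv_scores": ensemble.cv_scores.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_ensemble(path) -> ModelEnsemble:
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except (json.JSONDecodeError, OSError) as exc:
        raise IntegrityError(f"ensemble document unreadable: {exc}") from exc
    version = doc.get("format_version")
    if version != ENSEMBLE_FORMAT_VERSION:
        raise IntegrityError(
            f"ensemble format version {version!r} != supported {ENSEMBLE_FORMAT_VERSION}"
        )
    cfg_doc = dict(doc["config"])
    for key in ("lambda_grid", "meta_fields"):
        if cfg_doc.get(key) is not None:
            cfg_doc[key] = tuple(cfg_doc[key])
    config = PipelineConfig(**cfg_doc)
    fids = np.asarray(doc["model_feature_ids"], dtype=object)
    pos = {f: i for i, f in enumerate(fids)}
    models = []
    for md in doc["models"]:
        w = np.zeros(len(fids))
        for f, v in md["weights"].items():
            w[pos[f]] = v
        tuning = None if md["tuning"] is None else pd.DataFrame(md["tuning"])
        models.append(
            (
                md["repetition"],
                md["fold"],
                LinearModel(
                    feature_ids=fids,
                    weights=w,
                    intercept=md["intercept"],
                    lam=md["lambda"],
                    control_case_weight=config.control_case_weight,
                    tuning=tuning,
                    fallback=md["fallback"],
                ),
            )
        )
    plan = CVPlan(
        folds=[
            [
                (np.asarray(tr, dtype=object), np.asarray(te, dtype=object))
                for tr, te in rep
            ]
            for rep in doc["plan"]["folds"]
        ],
        seed=doc["plan"]["seed"],
    )
    return ModelEnsemble(
        models=models,
        norm_state=_state_from_doc(doc["normalization"]),
        plan=plan,
        config=config,
        sample_ids=np.asarray(doc["sample_ids"], dtype=object),
        labels=np.asarray(doc["labels"], dtype=int),
        score_matrix=np.asarray(doc["score_matrix"], dtype=float),
        cv_scores=np.asarray(doc["cv_scores"], dtype=float),
    )
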