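"""CV plans, LASSO fits, penalty tuning, ensemble bookkeeping, validation."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from crcmeta.errors import ConfigurationError, ContractError
from crcmeta.evaluation import roc_auc
from crcmeta.lasso import (
    PipelineConfig,
    augment_with_meta,
    build_meta_matrix,
    default_lambda_grid,
    external_validate,
    fit_lasso,
    make_cv_plan,
    run_cv_ensemble,
    train_baseline_logistic,
    tune_lambda,
)
from crcmeta.profiles import FeatureMatrix, log_transform
from crcmeta.synthetic import generate_cohort




def balanced_labels(n):
    y = pd.Series(np.r_[np.ones(n // 2, int), np.zeros(n - n // 2, int)],
                  index=[f"s{i}" for i in range(n)])
    return y


class TestCVPlan:
    def test_each_sample_in_exactly_one_test_fold_per_repetition(self):
        y = balanced_labels(47)
        plan = make_cv_plan(y, PipelineConfig(k_outer=5, n_repeats=3, seed=1))
        for rep in plan.folds:
            seen = [s for _, te in rep for s in te]
            assert sorted(seen) == sorted(y.index)

    def test_exact_stratification_with_balanced_classes(self):
        y = balanced_labels(100)
        plan = make_cv_plan(y, PipelineConfig(k_outer=10, n_repeats=1, seed=2))
        for _, te in plan.folds[0]:
            assert y.loc[list(te)].sum() == 5
            assert len(te) == 10

    def test_deterministic_and_seed_sensitive(self):
        y = balanced_labels(40)
        cfg = PipelineConfig(k_outer=5, n_repeats=2, seed=3)
        p1, p2 = make_cv_plan(y, cfg), make_cv_plan(y, cfg)
        assert [
            [sorted(te) for _, te in rep] for rep in p1.folds
        ] == [[sorted(te) for _, te in rep] for rep in p2.folds]
        distinct = {
            tuple(
                tuple(sorted(te))
                for rep in make_cv_plan(y, dataclasses.replace(cfg, seed=s)).folds
                for _, te in rep
            )
            for s in range(20)
        }
        assert len(distinct) == 20

    def test_small_class_rejected_with_hint(self):
        y = pd.Series([1] * 3 + [0] * 30, index=[f"s{i}" for i in range(33)])
        with pytest.raises(ContractError, match="smaller k"):
            make_cv_plan(y, PipelineConfig(k_outer=10))


class TestFitLasso:
    def make_data(self, n=80, p=10, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n, p))
        y = np.r_[np.ones(n // 2, int), np.zeros(n // 2, int)]
        X[:, 0] += 1.5 * y  # informative first feature
        X = (X - X.mean(0)) / X.std(0)
        return X, y

    def test_huge_penalty_zeroes_all_weights(self):
        X, y = self.make_data()
        m = fit_lasso(X, y, lam=1e6, control_case_weight=5.0)
        assert m.n_nonzero == 0

    def test_separable_direction_has_positive_weight(self):
        X, y = self.make_data()
        lam = default_lambda_grid(X, y, 5.0)[10]
        m = fit_lasso(X, y, lam, control_case_weight=5.0)
        assert m.weights[0] > 0

    def test_solution_beats_null_model_objective(self):
        X, y = self.make_data(seed=2)
        lam = default_lambda_grid(X, y, 5.0)[8]
        m = fit_lasso(X, y, lam, control_case_weight=5.0)

        def objective(w, b):
            z = X @ w + b
            loss = np.logaddexp(0, z) - y * z
            c = np.where(y == 0, 5.0, 1.0)
            return np.abs(w).sum() + (c * loss).sum() / lam

        assert objective(m.weights, m.intercept) <= objective(
            np.zeros(X.shape[1]), 0.0
        ) + 1e-9

    def test_nonfinite_rejected(self):
        X, y = self.make_data()
        X[0, 0] = np.nan
        with pytest.raises(Exception):
            fit_lasso(X, y, 1.0, 5.0)


class TestTuneLambda:
    def test_single_candidate_grid_returned(self):
        X, y = TestFitLasso().make_data()
        cfg = PipelineConfig(lambda_grid=(0.5,), k_inner=3, min_nonzero=1, seed=0)
        m = tune_lambda(X, y, cfg, seed=1)
        assert m.lam == 0.5

    def test_strong_signal_meets_min_nonzero(self, strong_cohort):
        from crcmeta.profiles import fit_normalization

        std, _ = fit_normalization(strong_cohort.matrix)
        X, y = std.values.T, strong_cohort.labels
        cfg = PipelineConfig(seed=0)
        m = tune_lambda(X, y, cfg, seed=3)
        assert m.n_nonzero >= 5
        assert not m.fallback
        assert m.tuning is not None and len(m.tuning) == cfg.n_lambda

    def test_empty_grid_rejected(self):
        with pytest.raises(ConfigurationError):
            PipelineConfig(lambda_grid=())


class TestEnsembleBookkeeping:
    def test_scores_are_mean_of_per_repetition_predictions(self, small_ensemble):
        assert small_ensemble.score_matrix.shape[1] == small_ensemble.config.n_repeats
        assert not np.isnan(small_ensemble.score_matrix).any()
        np.testing.assert_allclose(
            small_ensemble.cv_scores, small_ensemble.score_matrix.mean(axis=1)
        )

    def test_scores_in_unit_interval(self, small_ensemble):
        assert small_ensemble.score_matrix.min() >= 0.0
        assert small_ensemble.score_matrix.max() <= 1.0

    def test_model_count(self, small_ensemble):
        cfg = small_ensemble.config
        assert small_ensemble.n_models == cfg.k_outer * cfg.n_repeats

    def test_rerun_is_bit_identical(self, small_cohort, small_config, small_ensemble):
        again = run_cv_ensemble(small_cohort.matrix, small_cohort.metadata,
                                small_config)
        np.testing.assert_array_equal(again.score_matrix, small_ensemble.score_matrix)
        for (r1, k1, m1), (r2, k2, m2) in zip(again.models, small_ensemble.models):
            assert (r1, k1) == (r2, k2)
            np.testing.assert_array_equal(m1.weights, m2.weights)
            assert m1.intercept == m2.intercept


class TestExternalValidation:
    def test_replication_cohort_auc_close_to_cv(self, small_cohort, small_ensemble):
        rep_cfg = dataclasses.replace(small_cohort.config, seed=1234)
        rep = generate_cohort(rep_cfg, cohort_id="rep")
        preds = external_validate(small_ensemble, rep.matrix)
        ext_auc = roc_auc(preds.mean_scores, rep.labels).auc
        cv_auc = roc_auc(small_ensemble.cv_scores, small_ensemble.labels).auc
        assert abs(ext_auc - cv_auc) < 0.08  # small-n fixture; tight check in acceptance

    def test_every_model_contributes(self, small_cohort, small_ensemble):
        preds = external_validate(small_ensemble, small_cohort.matrix)
        assert preds.per_model_scores.shape[1] == small_ensemble.n_models
        np.testing.assert_allclose(preds.mean_scores,
                                   preds.per_model_scores.mean(axis=1))

    def test_all_center_sample_scores_at_intercept_baseline(self, small_ensemble):
        state = small_ensemble.norm_state
        # raw values whose log10(x + x0) equals the frozen centers give
        # standardized zeros, so each model outputs sigmoid(intercept)
        raw_vals = np.clip(10.0 ** state.centers - state.x0, 0.0, None)
        raw_vals = raw_vals / max(1.0, raw_vals.sum() * 1.01)
        m = FeatureMatrix(
            feature_ids=state.feature_ids.copy(),
            sample_ids=np.array(["center"], dtype=object),
            values=raw_vals[:, None],
        )
        preds = external_validate(small_ensemble, m)
        expected = np.mean(
            [1 / (1 + np.exp(-mod.intercept)) for _, _, mod in small_ensemble.models]
        )
        # renormalization above shifts values slightly; allow small slack
        assert preds.mean_scores[0] == pytest.approx(expected, abs=0.05)

    def test_resubstitution_correlates_with_cv_scores(self, strong_cohort):
        cfg = PipelineConfig(k_outer=5, n_repeats=2, n_lambda=10, seed=5)
        ens = run_cv_ensemble(strong_cohort.matrix, strong_cohort.metadata, cfg)
        preds = external_validate(ens, strong_cohort.matrix)
        from scipy.stats import spearmanr

        order = {s: i for i, s in enumerate(preds.sample_ids)}
        idx = [order[s] for s in ens.sample_ids]
        rho = spearmanr(preds.mean_scores[idx], ens.cv_scores).statistic
        assert rho > 0.9


class TestMetaAugmentation:
    def test_adds_exactly_one_row_for_fobt(self, small_cohort):
        logged = log_transform(small_cohort.matrix)
        mixed = augment_with_meta(logged, small_cohort.metadata, ["fobt"])
        assert mixed.n_features == logged.n_features + 1
        assert "meta_fobt" in set(mixed.feature_ids)
        assert mixed.feature_space == "mixed"

    def test_unknown_field_rejected(self, small_cohort):
        logged = log_transform(small_cohort.matrix)
        with pytest.raises(ConfigurationError, match="smoking"):
            augment_with_meta(logged, small_cohort.metadata, ["smoking"])

    def test_perfect_fobt_dominates_microbiome_only(self, small_cohort):
        # make the screen perfectly informative, then the combined model
        # cannot do worse than abundances alone
        meta = small_cohort.metadata.table.copy()
        labels = np.asarray(
            meta["diagnosis_group"].str.startswith("crc").astype(int)
        )
        meta["fobt"] = np.where(labels == 1, "positive", "negative")
        from crcmeta.profiles import SampleMetadata

        md = SampleMetadata(meta.reset_index())
        cfg = PipelineConfig(k_outer=5, n_repeats=2, n_lambda=8, seed=8)
        plain = run_cv_ensemble(small_cohort.matrix, md, cfg)
        combo = run_cv_ensemble(
            small_cohort.matrix, md, dataclasses.replace(cfg, meta_fields=("fobt",))
        )
        auc_plain = roc_auc(plain.cv_scores, plain.labels).auc
        auc_combo = roc_auc(combo.cv_scores, combo.labels).auc
        assert auc_combo >= auc_plain - 0.01

    def test_meta_only_confounder_baseline_design(self, small_cohort):
        m = build_meta_matrix(small_cohort.metadata, ["gender", "age", "bmi"])
        assert sorted(m.feature_ids) == ["meta_age", "meta_bmi", "meta_gender"]
        assert m.feature_space == "meta"


class TestBaselineLogistic:
    def test_label_equal_predictor_is_perfect(self):
        y = balanced_labels(60)
        m = FeatureMatrix(
            feature_ids=np.array(["flag"], dtype=object),
            sample_ids=np.asarray(y.index, dtype=object),
            values=y.to_numpy(dtype=float)[None, :],
            stage="log",
            feature_space="meta",
        )
        preds = train_baseline_logistic(m, y, k=5, seed=0)
        assert roc_auc(preds.mean_scores, y.to_numpy()).auc == 1.0

    def test_pure_noise_is_near_chance(self):
        rng = np.random.default_rng(14)
        y = balanced_labels(200)
        m = FeatureMatrix(
            feature_ids=np.array([f"n{i}" for i in range(3)], dtype=object),
            sample_ids=np.asarray(y.index, dtype=object),
            values=rng.standard_normal((3, 200)),
            stage="log",
            feature_space="meta",
        )
        preds = train_baseline_logistic(m, y, k=10, seed=1)
        assert abs(roc_auc(preds.mean_scores, y.to_numpy()).auc - 0.5) < 0.1


class TestLeakageGuard:
    def test_perturbing_test_sample_leaves_fold_model_unchanged(self, small_cohort):
        cfg = PipelineConfig(k_outer=4, n_repeats=1, k_inner=3, n_lambda=6,
                             normalization="within-fold", seed=9)
        base = run_cv_ensemble(small_cohort.matrix, small_cohort.metadata, cfg)
        r, k = 0, 1
        _, test_ids = base.plan.folds[r][k]
        victim = test_ids[0]
        perturbed = small_cohort.matrix.copy()
        j = list(perturbed.sample_ids).index(victim)
        perturbed.values[:, j] = perturbed.values[:, j] * 0.5
        again = run_cv_ensemble(perturbed, small_cohort.metadata, cfg)
        m0 = next(m for rr, kk, m in base.models if (rr, kk) == (r, k))
        m1 = next(m for rr, kk, m in again.models if (rr, kk) == (r, k))
        np.testing.assert_array_equal(m0.weights, m1.weights)
        assert m0.intercept == m1.intercept
        assert m0.lam == m1.lam
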