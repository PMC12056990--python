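"""Z-normalization, SVMSMOTE, leak-free CV and the benchmark grid."""

import numpy as np
import pandas as pd
import pytest
from sklearn.model_selection import StratifiedKFold

from pathomics import synthetic
from pathomics.bench import (
    PipelineConfig,
    SVMSMOTE,
    ZScoreScaler,
    benchmark_grid,
    cv_evaluate,
    external_validate,
    summarize_grid,
    svmsmote_oversample,
    zscore,
)
from pathomics.synthetic import CohortSpec


def split_cohort(spec: CohortSpec):
    """One draw split in half: train and validation share the planted truth."""
    X, y, info = synthetic.generate_cohort(spec)
    h = spec.n_samples // 2
    return X[:h], y[:h], X[h:], y[h:], info


class TestZScore:
    def test_hand_computed_sample_sd(self):
        t = zscore(np.array([[1.0], [2.0], [3.0]]))
        assert np.allclose(t.transform([[1.0], [2.0], [3.0]]).ravel(),
                           [-1.0, 0.0, 1.0])

    def test_constant_column_maps_to_zero(self):
        t = zscore(np.full((5, 2), 7.0))
        assert not t.transform(np.full((3, 2), 7.0)).any()
        assert t.n_constant_ == 2

    def test_row_at_train_mean_maps_to_zero(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((20, 4))
        t = zscore(X)
        assert np.allclose(t.transform(X.mean(axis=0, keepdims=True)), 0.0)

    def test_training_columns_standardized(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((50, 3)) * 4 + 2
        Z = zscore(X).transform(X)
        assert np.allclose(Z.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(Z.std(axis=0, ddof=1), 1.0, atol=1e-12)


class TestSvmSmote:
    def test_balanced_input_unchanged(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((10, 3))
        y = np.array([0, 1] * 5)
        Xr, yr = svmsmote_oversample(X, y, seed=0)
        assert np.array_equal(Xr, X) and np.array_equal(yr, y)

    def test_counts_equalized(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(0, 1, (20, 4)), rng.normal(2, 1, (5, 4))])
        y = np.array([0] * 20 + [1] * 5)
        Xr, yr = svmsmote_oversample(X, y, seed=1)
        assert np.bincount(yr).tolist() == [20, 20]
        assert Xr.shape == (40, 4)

    def test_synthetic_points_are_convex_combinations(self):
        rng = np.random.default_rng(4)
        X = np.vstack([rng.normal(0, 1, (15, 3)), rng.normal(1.5, 1, (5, 3))])
        y = np.array([0] * 15 + [1] * 5)
        Xr, yr = svmsmote_oversample(X, y, seed=2)
        minority = X[y == 1]
        for s in Xr[len(X):]:
            ok = False
            for a in range(5):
                for b in range(5):
                    if a == b:
                        continue
                    d = minority[b] - minority[a]
                    lam = np.dot(s - minority[a], d) / np.dot(d, d)
                    if 0.0 <= lam <= 1.0 and np.allclose(
                            minority[a] + lam * d, s, atol=1e-9):
                        ok = True
            assert ok

    def test_singleton_minority_duplicates_with_warning(self):
        rng = np.random.default_rng(5)
        X = np.vstack([rng.standard_normal((6, 2)), [[5.0, 5.0]]])
        y = np.array([0] * 6 + [1])
        with pytest.warns(UserWarning, match="size 1"):
            Xr, yr = svmsmote_oversample(X, y, seed=3)
        assert np.bincount(yr).tolist() == [6, 6]
        assert np.allclose(Xr[len(X):], [5.0, 5.0])

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(6)
        X = np.vstack([rng.normal(0, 1, (12, 3)), rng.normal(1, 1, (4, 3))])
        y = np.array([0] * 12 + [1] * 4)
        a = svmsmote_oversample(X, y, seed=7)[0]
        b = svmsmote_oversample(X, y, seed=7)[0]
        assert np.array_equal(a, b)


class TestCvEvaluate:
    def test_perfectly_separable_feature_gives_auc_one(self):
        rng = np.random.default_rng(7)
        y = np.array([0, 1] * 30)
        X = np.column_stack([np.where(y == 1, 2.0, -2.0)
                             + rng.normal(0, 0.05, 60)])
        cfg = PipelineConfig(selector="anova_f", model="lda", n_features=1, seed=0)
        auc, _ = cv_evaluate(X, y, cfg)
        assert auc == 1.0

    def test_null_cohort_auc_near_chance(self):
        aucs = []
        for seed in range(5):
            X, y, _ = synthetic.generate_cohort(CohortSpec(
                n_samples=100, n_features=30, n_informative=0,
                effect_size=0.0, seed=seed))
            cfg = PipelineConfig(selector="anova_f", model="lda",
                                 n_features=5, seed=seed)
            aucs.append(cv_evaluate(X, y, cfg)[0])
        assert 0.4 <= float(np.median(aucs)) <= 0.6

    def test_sweep_reports_best_candidate(self):
        X, y, _ = synthetic.generate_cohort(CohortSpec(
            n_samples=120, n_features=40, n_informative=5,
            effect_size=2.0, seed=8))
        cfg = PipelineConfig(selector="anova_f", model="svm",
                             n_features="sweep", seed=8)
        auc, best_n = cv_evaluate(X, y, cfg)
        assert auc > 0.85
        assert best_n in (2, 5, 10, 15, 20, 30, 40)

    def test_leak_free_selection(self):
        # a feature equal to the labels only on the held-out rows must not help
        rng = np.random.default_rng(9)
        X = rng.standard_normal((100, 20))
        y = np.array([0, 1] * 50)
        leak = rng.standard_normal(100)
        skf = StratifiedKFold(5, shuffle=True, random_state=3)
        for _, te in skf.split(X, y):
            leak[te] = y[te]
        cfg = PipelineConfig(selector="anova_f", model="svm", n_features=5, seed=3)
        auc_leak, _ = cv_evaluate(np.column_stack([X, leak]), y, cfg)
        auc_base, _ = cv_evaluate(X, y, cfg)
        assert auc_leak <= auc_base + 0.05

    def test_config_validation(self):
        with pytest.raises(ValueError):
            PipelineConfig(selector="nope")
        with pytest.raises(ValueError):
            PipelineConfig(model="nope")
        with pytest.raises(ValueError):
            PipelineConfig(cv_folds=1)
        with pytest.raises(ValueError):
            PipelineConfig(n_features="many")


class TestExternalValidation:
    def test_generalizes_to_same_distribution(self):
        Xtr, ytr, Xva, yva, _ = split_cohort(CohortSpec(
            n_samples=300, n_features=50, n_informative=8,
            effect_size=2.0, seed=10))
        cfg = PipelineConfig(selector="anova_f", model="svm",
                             n_features=8, seed=10)
        cv_auc, _ = cv_evaluate(Xtr, ytr, cfg)
        ext = external_validate(Xtr, ytr, Xva, yva, cfg)
        assert abs(ext - cv_auc) <= 0.1

    def test_shuffled_validation_labels_near_chance(self):
        rng = np.random.default_rng(11)
        Xtr, ytr, Xva, yva, _ = split_cohort(CohortSpec(
            n_samples=300, n_features=30, n_informative=5,
            effect_size=2.0, seed=11))
        ext = external_validate(Xtr, ytr, Xva, rng.permutation(yva),
                                PipelineConfig(n_features=5, seed=11))
        assert 0.3 <= ext <= 0.7

    def test_column_mismatch_rejected(self):
        rng = np.random.default_rng(12)
        with pytest.raises(ValueError, match="different features"):
            external_validate(rng.standard_normal((20, 4)), [0, 1] * 10,
                              rng.standard_normal((10, 3)), [0, 1] * 5,
                              PipelineConfig(n_features=2))

    def test_single_class_validation_rejected(self):
        rng = np.random.default_rng(13)
        with pytest.raises(ValueError, match="single class"):
            external_validate(rng.standard_normal((20, 4)), [0, 1] * 10,
                              rng.standard_normal((10, 4)), [1] * 10,
                              PipelineConfig(n_features=2))


class TestGrid:
    def test_one_by_one_grid_matches_direct_calls(self):
        Xtr, ytr, Xva, yva, _ = split_cohort(CohortSpec(
            n_samples=200, n_features=20, n_informative=4,
            effect_size=1.5, seed=14))
        cfg = PipelineConfig(selector="anova_f", model="lda",
                             n_features=5, seed=14)
        res = benchmark_grid(Xtr, ytr, Xva, yva, models=("lda",),
                             selectors=("anova_f",), n_features=5, seed=14)
        cell = res.grid.iloc[0]
        cv_auc, best_n = cv_evaluate(Xtr, ytr, cfg)
        ext = external_validate(Xtr, ytr, Xva, yva, cfg, best_n=best_n)
        assert cell["cv_auc"] == pytest.approx(cv_auc)
        assert cell["external_auc"] == pytest.approx(ext)

    def test_summary_hand_computed_median_sd(self):
        grid = pd.DataFrame(dict(
            model=["m"] * 3, selector=["a", "b", "c"],
            cv_auc=[0.7, 0.7, 0.7], external_auc=[0.6, 0.61, 0.65],
            best_n=[5, 5, 5],
        ))
        s = summarize_grid(grid)
        assert s["median_auc"].iloc[0] == pytest.approx(0.61)
        assert s["sd_auc"].iloc[0] == pytest.approx(0.0264575, abs=1e-6)

    def test_grid_deterministic_under_seed(self):
        Xtr, ytr, Xva, yva, _ = split_cohort(CohortSpec(
            n_samples=160, n_features=15, n_informative=3,
            effect_size=1.0, seed=15))
        kwargs = dict(models=("lda", "decision_tree"),
                      selectors=("anova_f", "mutual_info"),
                      n_features=5, seed=15)
        a = benchmark_grid(Xtr, ytr, Xva, yva, **kwargs)
        b = benchmark_grid(Xtr, ytr, Xva, yva, **kwargs)
        assert a.grid.equals(b.grid)

    def test_auc_of_negated_scores_complements(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(16)
        y = np.array([0, 1] * 25)
        s = rng.standard_normal(50)
        assert roc_auc_score(y, s) + roc_auc_score(y, -s) == pytest.approx(1.0)
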