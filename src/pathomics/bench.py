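"""Leak-free selector × classifier benchmark harness.

Per cross-validation fold, everything data-dependent — z-normalization,
relevance scoring, the choice of the top-n features, and boundary-aware
minority oversampling — is fitted on the training part only; the
held-out part is scored with continuous decision scores and summarized
by AUC.  A second cohort provides external validation: the pipeline is
refit once on the full training cohort and applied unchanged.  The full
model × selector grid shares one fold split, and per-model medians over
selectors summarize the grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin, clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier, NearestNeighbors
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from .selection import SCORERS, score_features, select_top

__all__ = [
    "MODELS",
    "PipelineConfig",
    "BenchmarkResult",
    "ZScoreScaler",
    "SVMSMOTE",
    "zscore",
    "svmsmote_oversample",
    "cv_evaluate",
    "external_validate",
    "benchmark_grid",
    "summarize_grid",
    "DEFAULT_N_FEATURES_GRID",
]

DEFAULT_N_FEATURES_GRID = (2, 5, 10, 15, 20, 30)


def _make_model(name: str, seed: int):
    factories = {
        "adaboost": lambda: AdaBoostClassifier(random_state=seed),
        "decision_tree": lambda: DecisionTreeClassifier(random_state=seed),
        "random_forest": lambda: RandomForestClassifier(random_state=seed),
        "lda": lambda: LinearDiscriminantAnalysis(),
        "svm": lambda: SVC(random_state=seed),
        "knn": lambda: KNeighborsClassifier(),
        "xgboost": lambda: XGBClassifier(
            random_state=seed, n_jobs=1, verbosity=0, eval_metric="logloss"
        ),
    }
    if name not in factories:
        raise ValueError(f"unknown model {name!r}")
    return factories[name]()


MODELS = ("adaboost", "decision_tree", "random_forest", "lda", "svm", "knn", "xgboost")


@dataclass(frozen=True)
class PipelineConfig:
    """One cell of the benchmark: a selector, a model and CV settings."""

    selector: str = "anova_f"
    model: str = "svm"
    n_features: int | str = "sweep"
    oversample: bool = True
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.selector not in SCORERS:
            raise ValueError(f"unknown selector {self.selector!r}")
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be at least 2")
        if isinstance(self.n_features, str) and self.n_features != "sweep":
            raise ValueError("n_features must be an integer or 'sweep'")


@dataclass
class BenchmarkResult:
    """Grid of per-cell AUCs plus per-model summaries over selectors."""

    grid: pd.DataFrame  # columns: model, selector, cv_auc, external_auc, best_n
    summary: pd.DataFrame  # per-model median/sd of external AUC


class ZScoreScaler(TransformerMixin, BaseEstimator):
    """Column standardization with the sample (n−1) standard deviation.

    Zero-variance columns are centered only (scale fixed at 1), so a
    constant training column maps to all zeros everywhere.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.shape[0] < 2:
            raise ValueError("need at least 2 training samples")
        self.center_ = X.mean(axis=0)
        scale = X.std(axis=0, ddof=1)
        self.n_constant_ = int((scale == 0).sum())
        scale[scale == 0] = 1.0
        self.scale_ = scale
        return self

    def transform(self, X):
        return (np.asarray(X, dtype=float) - self.center_) / self.scale_


def zscore(X_train: np.ndarray) -> ZScoreScaler:
    """Fit a z-transform on training data; apply with ``.transform``."""
    return ZScoreScaler().fit(X_train)


class SVMSMOTE(BaseEstimator):
    """Boundary-aware SMOTE: oversample the minority class near an SVM margin.

    An SVC is fitted to locate minority support vectors (the samples
    near the decision boundary); each synthetic sample is a convex
    combination ``x + λ(x_nn − x)``, λ ∈ (0, 1), of such a support
    vector and one of its ``k_neighbors`` nearest minority neighbors.
    Class counts are equal after resampling.  A minority class of size 1
    falls back to duplication with a warning.
    """

    def __init__(self, k_neighbors: int = 5, random_state: int = 0):
        self.k_neighbors = k_neighbors
        self.random_state = random_state

    def fit_resample(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        if classes.size != 2:
            raise ValueError("exactly two classes are required")
        if counts[0] == counts[1]:
            return X.copy(), y.copy()

        minority = classes[np.argmin(counts)]
        n_needed = int(abs(counts[0] - counts[1]))
        X_min = X[y == minority]
        rng = np.random.default_rng(self.random_state)

        if X_min.shape[0] == 1:
            warnings.warn("minority class of size 1: duplicating instead of "
                          "interpolating", stacklevel=2)
            synth = np.repeat(X_min, n_needed, axis=0)
        else:
            svc = SVC(kernel="rbf", random_state=self.random_state)
            svc.fit(X, y)
            sv = svc.support_[y[svc.support_] == minority]
            seeds = X[sv] if sv.size else X_min

            k = min(self.k_neighbors, X_min.shape[0] - 1)
            nn = NearestNeighbors(n_neighbors=k + 1).fit(X_min)
            _, nbrs = nn.kneighbors(seeds)

            pick_seed = rng.integers(0, seeds.shape[0], n_needed)
            pick_nbr = rng.integers(1, k + 1, n_needed)  # skip self
            lam = rng.uniform(0.0, 1.0, n_needed)[:, None]
            base = seeds[pick_seed]
            neigh = X_min[nbrs[pick_seed, pick_nbr]]
            synth = base + lam * (neigh - base)

        X_out = np.vstack([X, synth])
        y_out = np.concatenate([y, np.full(n_needed, minority, dtype=y.dtype)])
        return X_out, y_out


def svmsmote_oversample(X, y, seed: int = 0):
    """Functional form of :class:`SVMSMOTE`."""
    return SVMSMOTE(random_state=seed).fit_resample(X, y)


def _decision_scores(model, X) -> np.ndarray:
    if hasattr(model, "decision_function"):
        return np.asarray(model.decision_function(X), dtype=float)
    return np.asarray(model.predict_proba(X)[:, 1], dtype=float)


def _fit_cell(X_train, y_train, config: PipelineConfig, n: int, fold_seed: int):
    """Fit scaler → selector → oversampler → model on one training set."""
    scaler = ZScoreScaler().fit(X_train)
    Xt = scaler.transform(X_train)
    scores = score_features(Xt, y_train, config.selector)
    cols = select_top(scores, min(n, Xt.shape[1]))
    Xs, ys = Xt[:, cols], y_train
    if config.oversample:
        Xs, ys = SVMSMOTE(random_state=fold_seed).fit_resample(Xs, ys)
    model = _make_model(config.model, config.seed)
    model.fit(Xs, ys)
    positive = np.unique(y_train).max()

    def predict(X_new):
        s = _decision_scores(model, scaler.transform(X_new)[:, cols])
        # ensure scores are oriented toward the positive class
        if hasattr(model, "classes_") and model.classes_[-1] != positive:
            s = -s
        return s

    return predict, cols


def _candidate_grid(config: PipelineConfig, p: int) -> list[int]:
    if config.n_features == "sweep":
        grid = sorted({n for n in DEFAULT_N_FEATURES_GRID if n <= p} | {p})
    else:
        grid = [min(int(config.n_features), p)]
    return grid


def cv_evaluate(X, y, config: PipelineConfig) -> tuple[float, int]:
    """Stratified cross-validated AUC with per-fold selection.

    When ``config.n_features == "sweep"``, every candidate feature count
    is evaluated on the same folds and the count maximizing the mean
    out-of-fold AUC is reported (smallest count on ties).
    Returns ``(cv_auc, best_n_features)``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    skf = StratifiedKFold(n_splits=config.cv_folds, shuffle=True,
                          random_state=config.seed)
    grid = _candidate_grid(config, X.shape[1])
    fold_aucs = {n: [] for n in grid}
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        if np.unique(y[tr]).size < 2 or np.unique(y[te]).size < 2:
            raise ValueError("a fold lost one of the classes; reduce cv_folds")
        for n in grid:
            predict, _ = _fit_cell(X[tr], y[tr], config, n,
                                   fold_seed=config.seed + fold)
            fold_aucs[n].append(roc_auc_score(y[te], predict(X[te])))
    means = {n: float(np.mean(v)) for n, v in fold_aucs.items()}
    best_n = min(means, key=lambda n: (-means[n], n))
    return means[best_n], best_n


def external_validate(X_train, y_train, X_valid, y_valid,
                      config: PipelineConfig,
                      best_n: int | None = None) -> float:
    """Refit on the full training cohort; score the validation cohort once.

    ``best_n`` short-circuits the sweep when the feature count has
    already been chosen by :func:`cv_evaluate`.
    """
    X_train = np.asarray(X_train, dtype=float)
    X_valid = np.asarray(X_valid, dtype=float)
    if X_train.shape[1] != X_valid.shape[1]:
        raise ValueError("training and validation cohorts have different features")
    y_valid = np.asarray(y_valid)
    if np.unique(y_valid).size < 2:
        raise ValueError("validation labels contain a single class: AUC undefined")
    if best_n is None:
        if config.n_features == "sweep":
            _, best_n = cv_evaluate(X_train, y_train, config)
        else:
            best_n = int(config.n_features)
    predict, _ = _fit_cell(X_train, np.asarray(y_train), config, best_n,
                           fold_seed=config.seed)
    return float(roc_auc_score(y_valid, predict(X_valid)))


def summarize_grid(grid: pd.DataFrame) -> pd.DataFrame:
    """Per-model median and sample sd of external AUC across selectors."""
    return (
        grid.groupby("model")["external_auc"]
        .agg(median_auc="median", sd_auc=lambda s: s.std(ddof=1))
        .reset_index()
    )


def benchmark_grid(
    X_train, y_train, X_valid, y_valid,
    models: tuple[str, ...] = MODELS,
    selectors: tuple[str, ...] = SCORERS,
    n_features: int | str = "sweep",
    oversample: bool = True,
    cv_folds: int = 5,
    seed: int = 0,
) -> BenchmarkResult:
    """Evaluate every model × selector cell with a shared fold split.

    Failed cells are recorded as missing (NaN) rather than aborting the
    grid.  The summary holds per-model median and standard deviation of
    the external AUC across selectors.
    """
    rows = []
    for model in models:
        for selector in selectors:
            config = PipelineConfig(selector=selector, model=model,
                                    n_features=n_features, oversample=oversample,
                                    cv_folds=cv_folds, seed=seed)
            try:
                cv_auc, best_n = cv_evaluate(X_train, y_train, config)
                ext_auc = external_validate(X_train, y_train, X_valid, y_valid,
                                            config, best_n=best_n)
            except Exception as exc:  # failed cell: record, keep going
                warnings.warn(f"cell ({model}, {selector}) failed: {exc}",
                              stacklevel=2)
                cv_auc, ext_auc, best_n = np.nan, np.nan, -1
            rows.append(dict(model=model, selector=selector, cv_auc=cv_auc,
                             external_auc=ext_auc, best_n=best_n))
    grid = pd.DataFrame(rows)
    return BenchmarkResult(grid=grid, summary=summarize_grid(grid))
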