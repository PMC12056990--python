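"""Redundancy filtering and feature-relevance scoring.

Two stages: (1) a greedy Spearman redundancy filter dropping any feature
whose absolute rank correlation with an already-retained feature exceeds
a threshold (default 0.9); (2) relevance scoring by one of six methods —
ANOVA F-test, mutual information (equal-frequency binning), and the
Relief family (ReliefF, SURF, SURF*, MultiSURF) implemented from their
update-rule definitions.

Relief scores use the range-normalized feature difference
``diff(f, a, b) = |a_f − b_f| / range_f`` and Manhattan distances on
z-scored features, making every score invariant to affine rescaling of
any feature.  Iteration runs over all samples in order (deterministic);
seeded subsampling is available.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin, f_classif
from sklearn.metrics import mutual_info_score
from sklearn.utils.validation import check_is_fitted, validate_data

__all__ = [
    "SelectionScores",
    "SCORERS",
    "RELIEF_VARIANTS",
    "spearman_filter",
    "anova_f_scores",
    "mutual_info_scores",
    "relief_scores",
    "select_top",
    "score_features",
    "SpearmanRedundancyFilter",
    "RankingFeatureSelector",
]

RELIEF_VARIANTS = ("relieff", "surf", "surfstar", "multisurf")
SCORERS = ("anova_f", "mutual_info") + RELIEF_VARIANTS


@dataclass
class SelectionScores:
    """Per-feature relevance scores from one method, with ranking."""

    method: str
    scores: np.ndarray
    ranking: np.ndarray  # feature indices by descending score
    selected_k: int | None = None

    def __post_init__(self) -> None:
        if self.selected_k is not None and self.selected_k > self.scores.size:
            raise ValueError("selected_k exceeds the number of features")


def _rank_descending(scores: np.ndarray) -> np.ndarray:
    """Indices sorted by descending score; ties broken by feature index."""
    return np.lexsort((np.arange(scores.size), -scores))


def _check_two_classes(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("exactly two classes are required")
    return classes


# ---------------------------------------------------------------------------
# redundancy filter
# ---------------------------------------------------------------------------


def spearman_filter(X: np.ndarray, threshold: float = 0.9) -> np.ndarray:
    """Greedy Spearman redundancy filter.

    Scanning columns left to right, a feature is dropped when its
    absolute Spearman correlation with any already-retained feature is
    strictly above ``threshold``.  Constant features (correlation
    undefined) are treated as correlation 0 and retained.
    Returns the retained column indices in order.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 samples")
    p = X.shape[1]
    if p == 1:
        return np.array([0])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = stats.spearmanr(X).statistic
    if np.ndim(rho) == 0:  # spearmanr collapses the 2-column case to a scalar
        r = float(np.nan_to_num(rho, nan=0.0))
        rho = np.array([[1.0, r], [r, 1.0]])
    else:
        rho = np.nan_to_num(rho, nan=0.0)
    retained: list[int] = []
    for j in range(p):
        if all(abs(rho[j, k]) <= threshold for k in retained):
            retained.append(j)
    return np.asarray(retained, dtype=int)


# ---------------------------------------------------------------------------
# univariate scorers
# ---------------------------------------------------------------------------


def anova_f_scores(X: np.ndarray, y: np.ndarray) -> SelectionScores:
    """One-way ANOVA F statistic per feature (between/within mean squares)."""
    _check_two_classes(y)
    X = np.asarray(X, dtype=float)
    F, _ = f_classif(X, y)
    F = np.nan_to_num(F, nan=0.0)
    return SelectionScores("anova_f", F, _rank_descending(F))


def mutual_info_scores(
    X: np.ndarray,
    y: np.ndarray,
    n_bins: int | None = None,
) -> SelectionScores:
    """Mutual information (bits) between each binned feature and the label.

    Features are discretized by equal-frequency binning with
    ``ceil(sqrt(n))`` bins by default; duplicate quantile edges collapse,
    so low-cardinality features keep their natural levels.
    """
    _check_two_classes(y)
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n_bins is None:
        n_bins = math.ceil(math.sqrt(n))
    scores = np.empty(X.shape[1])
    qs = np.linspace(0.0, 1.0, n_bins + 1)
    for j in range(X.shape[1]):
        edges = np.unique(np.quantile(X[:, j], qs))
        if edges.size <= 2:
            binned = (X[:, j] > edges[0]).astype(int) if edges.size == 2 else \
                np.zeros(n, dtype=int)
        else:
            binned = np.searchsorted(edges[1:-1], X[:, j], side="right")
        scores[j] = mutual_info_score(binned, y) / math.log(2.0)
    return SelectionScores("mutual_info", scores, _rank_descending(scores))


# ---------------------------------------------------------------------------
# Relief family
# ---------------------------------------------------------------------------


def relief_scores(
    X: np.ndarray,
    y: np.ndarray,
    variant: str = "relieff",
    k_neighbors: int = 10,
    n_iterations: int | None = None,
    seed: int | None = None,
) -> SelectionScores:
    """Relief-family relevance scores.

    For each target instance the feature weight is raised by the mean
    range-normalized difference to the selected misses and lowered by the
    mean difference to the selected hits, averaged over targets.  The
    neighbor rule depends on the variant:

    - ``relieff``: the ``k_neighbors`` nearest hits and nearest misses;
    - ``surf``: all instances within T = mean pairwise distance;
    - ``surfstar``: as SURF, plus instances beyond T with inverted sign;
    - ``multisurf``: instances within the per-target threshold
      ``T_i = mean_i − sd_i/2`` of the target's distance distribution.

    Distances are Manhattan on z-scored features.
    """
    if variant not in RELIEF_VARIANTS:
        raise ValueError(f"unknown Relief variant {variant!r}")
    _check_two_classes(y)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, p = X.shape

    frange = np.ptp(X, axis=0)
    frange[frange == 0] = 1.0  # constant feature: diff is 0 anyway

    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Xz = (X - X.mean(axis=0)) / sd
    D = cdist(Xz, Xz, metric="cityblock")
    np.fill_diagonal(D, np.inf)

    if n_iterations is None or n_iterations >= n:
        targets = np.arange(n)
    else:
        rng = np.random.default_rng(seed)
        targets = rng.choice(n, size=n_iterations, replace=False)
    m = targets.size

    if variant in ("surf", "surfstar"):
        finite = np.isfinite(D)
        T_global = D[finite].mean()

    W = np.zeros(p)
    for i in targets:
        same = y == y[i]
        same[i] = False
        other = ~same
        other[i] = False
        diffs = np.abs(X - X[i]) / frange  # (n, p)

        if variant == "relieff":
            hit_idx = np.flatnonzero(same)
            miss_idx = np.flatnonzero(other)
            k_h = min(k_neighbors, hit_idx.size)
            k_m = min(k_neighbors, miss_idx.size)
            if k_h < k_neighbors or k_m < k_neighbors:
                warnings.warn("k_neighbors clamped to class size - 1", stacklevel=2)
            if k_h == 0 or k_m == 0:
                continue
            hits = hit_idx[np.argsort(D[i, hit_idx], kind="stable")[:k_h]]
            misses = miss_idx[np.argsort(D[i, miss_idx], kind="stable")[:k_m]]
            W += diffs[misses].mean(axis=0) - diffs[hits].mean(axis=0)
        else:
            if variant == "multisurf":
                d_i = D[i][np.isfinite(D[i])]
                T_i = d_i.mean() - d_i.std(ddof=0) / 2.0
            else:
                T_i = T_global
            near = D[i] < T_i
            near_hits = near & same
            near_miss = near & other
            if near_hits.any():
                W -= diffs[near_hits].mean(axis=0)
            if near_miss.any():
                W += diffs[near_miss].mean(axis=0)
            if variant == "surfstar":
                far = np.isfinite(D[i]) & ~near
                far_hits = far & same
                far_miss = far & other
                if far_hits.any():
                    W += diffs[far_hits].mean(axis=0)
                if far_miss.any():
                    W -= diffs[far_miss].mean(axis=0)
    W /= m
    return SelectionScores(variant, W, _rank_descending(W))


# ---------------------------------------------------------------------------
# dispatch and top-m selection
# ---------------------------------------------------------------------------


def score_features(
    X: np.ndarray,
    y: np.ndarray,
    method: str,
    **kwargs,
) -> SelectionScores:
    """Dispatch to one of the registered scoring methods by name."""
    if method == "anova_f":
        return anova_f_scores(X, y)
    if method == "mutual_info":
        return mutual_info_scores(X, y, **kwargs)
    if method in RELIEF_VARIANTS:
        return relief_scores(X, y, variant=method, **kwargs)
    raise ValueError(f"unknown selection method {method!r}")


def select_top(scores: SelectionScores, m: int) -> np.ndarray:
    """The first ``m`` feature indices of the ranking (deterministic ties)."""
    if not 1 <= m <= scores.scores.size:
        raise ValueError("m out of range")
    return scores.ranking[:m].copy()


# ---------------------------------------------------------------------------
# sklearn-compatible estimators
# ---------------------------------------------------------------------------


class SpearmanRedundancyFilter(SelectorMixin, BaseEstimator):
    """Transformer form of the greedy Spearman redundancy filter."""

    def __init__(self, threshold: float = 0.9):
        self.threshold = threshold

    def fit(self, X, y=None):
        X = validate_data(self, X, ensure_min_samples=2)
        self.retained_ = spearman_filter(X, self.threshold)
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.retained_] = True
        return mask


class RankingFeatureSelector(SelectorMixin, BaseEstimator):
    """Select the top-``n_features`` columns by one scoring method.

    Fitted attributes: ``scores_`` (per input feature), ``ranking_``
    (indices by descending score, index-order tie-break) and the boolean
    support mask.
    """

    def __init__(self, method: str = "anova_f", n_features: int = 10,
                 k_neighbors: int = 10, seed: int | None = None):
        self.method = method
        self.n_features = n_features
        self.k_neighbors = k_neighbors
        self.seed = seed

    def fit(self, X, y):
        X = validate_data(self, X, ensure_min_samples=2)
        kwargs = {}
        if self.method in RELIEF_VARIANTS:
            kwargs = dict(k_neighbors=self.k_neighbors, seed=self.seed)
        result = score_features(X, np.asarray(y), self.method, **kwargs)
        self.scores_ = result.scores
        self.ranking_ = result.ranking
        self.selected_ = select_top(result, min(self.n_features, X.shape[1]))
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.selected_] = True
        return mask
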