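"""GLCM Haralick texture features on cell-density maps.

Each density-map raster is quantized to a small number of gray levels
and four symmetric gray-level co-occurrence matrices are accumulated,
one per pixel-adjacency orientation:

    horizontal      offset (0, +1)
    vertical        offset (+1, 0)
    minor diagonal  offset (+1, +1)
    major diagonal  offset (+1, -1)

From each GLCM the 13 classical Haralick statistics are computed
(energy/ASM, contrast, correlation, sum of squares, inverse difference
moment, sum average, sum variance, sum entropy, entropy, difference
variance, difference entropy, and the two information measures of
correlation), giving 52 features per patch.  Slide-level vectors
summarize each of the 52 features over a slide's accepted patches with
five statistics (mean, median, variance, kurtosis, skewness): 260
features per slide.

Conventions: entropies use log base 2 with 0·log0 := 0; variance uses
the n−1 denominator; kurtosis is Fisher excess and skewness the adjusted
Fisher–Pearson form, both 0 for degenerate samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "GLCM",
    "ORIENTATIONS",
    "HARALICK_NAMES",
    "SLIDE_STATS",
    "quantize",
    "compute_glcm",
    "haralick13",
    "patch_features",
    "slide_aggregate",
    "HaralickTextureExtractor",
]

ORIENTATIONS: dict[str, tuple[int, int]] = {
    "horizontal": (0, 1),
    "vertical": (1, 0),
    "minor_diagonal": (1, 1),
    "major_diagonal": (1, -1),
}

HARALICK_NAMES = (
    "asm",
    "contrast",
    "correlation",
    "sum_of_squares",
    "idm",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "difference_variance",
    "difference_entropy",
    "imc1",
    "imc2",
)

SLIDE_STATS = ("mean", "median", "variance", "kurtosis", "skewness")

DEFAULT_LEVELS = 32


@dataclass
class GLCM:
    """A normalized, symmetric gray-level co-occurrence matrix."""

    matrix: np.ndarray  # (levels, levels), sums to 1
    levels: int
    orientation: str
    distance: int = 1


def quantize(raster: np.ndarray, levels: int = DEFAULT_LEVELS) -> np.ndarray:
    """Quantize an 8-bit raster onto ``levels`` gray levels (0..levels-1)."""
    arr = np.asarray(raster)
    if arr.dtype != np.uint8:
        if arr.min() < 0 or arr.max() > 255:
            raise ValueError("expected values in [0, 255]")
        arr = arr.astype(np.uint8)
    return ((arr.astype(np.int64) * levels) // 256).astype(np.int64)


def compute_glcm(
    raster: np.ndarray,
    orientation: str,
    levels: int = DEFAULT_LEVELS,
    distance: int = 1,
) -> GLCM:
    """Accumulate a symmetric co-occurrence matrix for one orientation.

    ``raster`` must already be quantized (integer values < ``levels``).
    Counts for the orientation's pixel offset are accumulated in both
    directions and normalized to sum to 1.
    """
    if orientation not in ORIENTATIONS:
        raise ValueError(f"unknown orientation {orientation!r}")
    q = np.asarray(raster)
    if q.ndim != 2:
        raise ValueError("expected a 2-D raster")
    if q.min() < 0 or q.max() >= levels:
        raise ValueError("raster is not quantized to the requested levels")
    dr, dc = ORIENTATIONS[orientation]
    dr, dc = dr * distance, dc * distance
    h, w = q.shape
    if h - abs(dr) < 1 or w - abs(dc) < 1 or (h - abs(dr)) * (w - abs(dc)) == 0:
        raise ValueError("raster too small for the requested offset")

    a = q[max(0, -dr): h - max(0, dr), max(0, -dc): w - max(0, dc)]
    b = q[max(0, dr): h - max(0, -dr), max(0, dc): w - max(0, -dc)]
    if a.size == 0:
        raise ValueError("raster too small for the requested offset")

    pairs = np.bincount((a * levels + b).ravel(), minlength=levels * levels)
    counts = pairs.reshape(levels, levels).astype(float)
    counts = counts + counts.T  # symmetric accumulation
    total = counts.sum()
    return GLCM(matrix=counts / total, levels=levels,
                orientation=orientation, distance=distance)


def _xlog2(p: np.ndarray) -> np.ndarray:
    """p * log2(p) with the 0·log0 := 0 convention."""
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def haralick13(glcm: GLCM | np.ndarray) -> np.ndarray:
    """The 13 classical Haralick statistics of a normalized GLCM.

    Degenerate denominators (zero marginal variance for correlation, zero
    marginal entropy for the first information measure) yield 0 so every
    output is finite.
    """
    P = glcm.matrix if isinstance(glcm, GLCM) else np.asarray(glcm, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("GLCM must be square")
    if not np.isclose(P.sum(), 1.0, atol=1e-8):
        raise ValueError("GLCM must be normalized to sum 1")

    L = P.shape[0]
    i = np.arange(L)
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = float(i @ px)
    mu_y = float(i @ py)
    sd_x = float(np.sqrt(((i - mu_x) ** 2) @ px))
    sd_y = float(np.sqrt(((i - mu_y) ** 2) @ py))

    ii, jj = np.meshgrid(i, i, indexing="ij")

    # marginal distributions of i+j and |i-j|
    p_sum = np.bincount((ii + jj).ravel(), weights=P.ravel(), minlength=2 * L - 1)
    p_diff = np.bincount(np.abs(ii - jj).ravel(), weights=P.ravel(), minlength=L)
    k_sum = np.arange(2 * L - 1)
    k_diff = np.arange(L)

    asm = float((P ** 2).sum())
    contrast = float((k_diff ** 2) @ p_diff)
    if sd_x > 0 and sd_y > 0:
        correlation = float(((ii * jj * P).sum() - mu_x * mu_y) / (sd_x * sd_y))
    else:
        correlation = 0.0
    sum_of_squares = float((((ii - mu_x) ** 2) * P).sum())
    idm = float((P / (1.0 + (ii - jj) ** 2)).sum())
    sum_average = float(k_sum @ p_sum)
    sum_variance = float(((k_sum - sum_average) ** 2) @ p_sum)
    sum_entropy = float(-_xlog2(p_sum).sum())
    entropy = float(-_xlog2(P).sum())
    mu_diff = float(k_diff @ p_diff)
    difference_variance = float(((k_diff - mu_diff) ** 2) @ p_diff)
    difference_entropy = float(-_xlog2(p_diff).sum())

    hx = float(-_xlog2(px).sum())
    hy = float(-_xlog2(py).sum())
    pxpy = np.outer(px, py)
    nz = pxpy > 0
    hxy1 = float(-(P[nz] * np.log2(pxpy[nz])).sum())
    hxy2 = float(-_xlog2(pxpy).sum())
    denom = max(hx, hy)
    imc1 = float((entropy - hxy1) / denom) if denom > 0 else 0.0
    arg = 1.0 - np.exp(-2.0 * (hxy2 - entropy))
    imc2 = float(np.sqrt(max(arg, 0.0)))

    return np.array([
        asm, contrast, correlation, sum_of_squares, idm, sum_average,
        sum_variance, sum_entropy, entropy, difference_variance,
        difference_entropy, imc1, imc2,
    ])


def patch_feature_names() -> list[str]:
    return [f"{feat}_{orient}" for orient in ORIENTATIONS for feat in HARALICK_NAMES]


def patch_features(
    density_raster: np.ndarray,
    levels: int = DEFAULT_LEVELS,
    distance: int = 1,
    prequantized: bool = False,
) -> pd.Series:
    """52 Haralick features (13 × 4 orientations) of one density map.

    Accepts either the 8-bit ``gray`` raster of a density map (default)
    or an already-quantized raster (``prequantized=True``).
    """
    raster = np.asarray(density_raster)
    q = raster if prequantized else quantize(raster, levels)
    values = np.concatenate([
        haralick13(compute_glcm(q, orient, levels=levels, distance=distance))
        for orient in ORIENTATIONS
    ])
    return pd.Series(values, index=patch_feature_names())


def slide_feature_names() -> list[str]:
    return [f"{name}_{stat}" for name in patch_feature_names() for stat in SLIDE_STATS]


def slide_aggregate(
    patch_vectors: list[pd.Series] | pd.DataFrame,
    slide_id: str | None = None,
) -> pd.Series:
    """Summarize a slide's patch features into the 260-length vector.

    Each of the 52 patch features is reduced over patches with mean,
    median, sample variance, excess kurtosis and adjusted skewness.
    Degenerate samples (a single patch, or zero spread) yield 0 for
    variance/kurtosis/skewness.  An empty patch list is an error: the
    slide is unusable.
    """
    if isinstance(patch_vectors, pd.DataFrame):
        df = patch_vectors
    else:
        if len(patch_vectors) == 0:
            raise ValueError("cannot aggregate an empty patch list")
        df = pd.DataFrame(patch_vectors)
    if df.shape[0] == 0:
        raise ValueError("cannot aggregate an empty patch list")

    X = df.to_numpy(dtype=float)
    n = X.shape[0]
    mean = X.mean(axis=0)
    median = np.median(X, axis=0)
    if n > 1:
        variance = X.var(axis=0, ddof=1)
    else:
        variance = np.zeros(X.shape[1])
    spread = variance > 0
    kurt = np.zeros(X.shape[1])
    skew = np.zeros(X.shape[1])
    if n > 3:
        kurt[spread] = stats.kurtosis(X[:, spread], axis=0, fisher=True, bias=False)
    if n > 2:
        skew[spread] = stats.skew(X[:, spread], axis=0, bias=False)

    out = {}
    stats_map = dict(mean=mean, median=median, variance=variance,
                     kurtosis=kurt, skewness=skew)
    for j, name in enumerate(df.columns):
        for stat in SLIDE_STATS:
            out[f"{name}_{stat}"] = float(stats_map[stat][j])
    series = pd.Series(out)
    series.name = slide_id
    return series


class HaralickTextureExtractor(TransformerMixin, BaseEstimator):
    """Transformer mapping density-map rasters to 52-feature vectors.

    ``transform`` takes a list of 2-D 8-bit rasters and returns a
    DataFrame with one row per raster; stateless (``fit`` is a no-op),
    provided so texture extraction composes with sklearn pipelines.
    """

    def __init__(self, levels: int = DEFAULT_LEVELS, distance: int = 1):
        self.levels = levels
        self.distance = distance

    def fit(self, X, y=None):
        self.n_features_out_ = len(ORIENTATIONS) * len(HARALICK_NAMES)
        return self

    def transform(self, X) -> pd.DataFrame:
        rows = [patch_features(r, levels=self.levels, distance=self.distance)
                for r in X]
        return pd.DataFrame(rows).reset_index(drop=True)
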