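"""Synthetic data generators with known ground truth.

Every downstream stage of the pipeline (tissue masking, nuclei
segmentation, texture extraction, feature selection, benchmarking,
enrichment) is exercised on artificial inputs produced here.  Each
generator returns its ground truth alongside the artifact — nucleus
centers/radii and the exact pixel mask, the indices of informative
features, the names of planted gene sets — so recovery can be asserted
exactly.  All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

__all__ = [
    "NucleiSceneSpec",
    "CohortSpec",
    "ExpressionSpec",
    "PatchSample",
    "generate_patch",
    "generate_wsi",
    "generate_cohort",
    "generate_expression",
    "make_gene_sets",
]

# pink-ish H&E-like palette used for 3-channel rendering; tissue is kept
# clearly darker than the glass background so a global Otsu threshold on
# the grayscale separates tissue (with its nuclei) from background
_TISSUE_RGB = np.array([190.0, 115.0, 155.0])
_NUCLEUS_RGB = np.array([88.0, 62.0, 134.0])
_BACKGROUND_RGB = np.array([246.0, 244.0, 245.0])


@dataclass(frozen=True)
class NucleiSceneSpec:
    """Parameters of one synthetic nuclei scene (a patch-sized raster).

    Nuclei are rendered as anti-aliased dark disks on a brighter
    background; ``cluster_factor`` interpolates between uniform placement
    (0) and strongly clustered placement (1, nuclei scattered around a
    small number of cluster centers).
    """

    width_px: int = 512
    height_px: int = 512
    n_nuclei: int = 50
    radius_px_mean: float = 8.0
    radius_px_sd: float = 1.5
    cluster_factor: float = 0.0
    overlap_allowed: bool = True
    background_level: int = 220
    nucleus_level: int = 70
    noise_sd: float = 2.0
    seed: int = 0
    grayscale: bool = False

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("raster dimensions must be positive")
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be non-negative")
        if self.radius_px_mean <= 0 or self.radius_px_sd <= 0:
            raise ValueError("radius parameters must be positive")
        if not 0.0 <= self.cluster_factor <= 1.0:
            raise ValueError("cluster_factor must be in [0, 1]")
        for name in ("background_level", "nucleus_level"):
            v = getattr(self, name)
            if not 0 <= v <= 255:
                raise ValueError(f"{name} must be in [0, 255]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.radius_px_mean * 2 >= min(self.width_px, self.height_px):
            raise ValueError("nucleus radius too large for the raster")


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic slide-level feature cohort.

    ``n_informative`` features are shifted between the two classes by
    ``effect_size`` standard deviations; the rest are exchangeable
    standard-normal noise.  When ``correlated_block_rho`` > 0, a block of
    up to 10 non-informative features shares that pairwise Spearman
    correlation in expectation.
    """

    n_samples: int = 100
    n_features: int = 50
    n_informative: int = 5
    effect_size: float = 1.0
    class_balance: float = 0.5
    correlated_block_rho: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.n_features:
            raise ValueError("n_informative must not exceed n_features")
        if not 0.0 < self.class_balance < 1.0:
            raise ValueError("class_balance must lie strictly in (0, 1)")
        if not 0.0 <= self.correlated_block_rho < 1.0:
            raise ValueError("correlated_block_rho must be in [0, 1)")


@dataclass(frozen=True)
class ExpressionSpec:
    """Parameters of a synthetic log-expression matrix with planted sets."""

    n_genes: int = 200
    n_samples: int = 40
    gene_sets: dict = field(default_factory=dict)
    planted_up_sets: tuple = ()
    planted_down_sets: tuple = ()
    effect_size: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        universe = set(gene_id(i) for i in range(self.n_genes))
        for name in tuple(self.planted_up_sets) + tuple(self.planted_down_sets):
            if name not in self.gene_sets:
                raise ValueError(f"planted set {name!r} is not a known gene set")
        for name, members in self.gene_sets.items():
            missing = set(members) - universe
            if missing:
                raise ValueError(
                    f"gene set {name!r} references unknown genes: {sorted(missing)[:5]}"
                )


@dataclass
class PatchSample:
    """A rendered scene plus its ground truth."""

    image: np.ndarray
    centers: np.ndarray  # (n, 2) float, (row, col)
    radii: np.ndarray  # (n,) float
    mask: np.ndarray  # bool, union of nucleus disks


def gene_id(i: int) -> str:
    return f"g{i:04d}"


# ---------------------------------------------------------------------------
# image scenes
# ---------------------------------------------------------------------------


def _sample_centers(spec: NucleiSceneSpec, radii: np.ndarray,
                    rng: np.random.Generator) -> np.ndarray:
    """Place nucleus centers, honouring clustering and non-overlap."""
    h, w = spec.height_px, spec.width_px
    n = spec.n_nuclei
    if n == 0:
        return np.zeros((0, 2))

    # two-level clustering: cluster centers, then Gaussian scatter
    n_clusters = max(1, int(round(n / 8)))
    margin = float(np.ceil(radii.max())) + 1.0
    if margin * 2 >= min(h, w):
        raise ValueError("nucleus radius too large for the raster")
    cluster_centers = np.column_stack(
        [rng.uniform(margin, h - margin, n_clusters),
         rng.uniform(margin, w - margin, n_clusters)]
    )
    scatter_sd = 4.0 * spec.radius_px_mean

    centers: list[np.ndarray] = []
    max_attempts = 500
    for i in range(n):
        r = radii[i]
        for _ in range(max_attempts):
            if rng.uniform() < spec.cluster_factor:
                c = cluster_centers[rng.integers(n_clusters)]
                pos = c + rng.normal(0.0, scatter_sd, 2)
                pos = np.clip(pos, [r + 1, r + 1], [h - r - 1, w - r - 1])
            else:
                pos = np.array([rng.uniform(r + 1, h - r - 1),
                                rng.uniform(r + 1, w - r - 1)])
            if spec.overlap_allowed or not centers:
                centers.append(pos)
                break
            d = np.linalg.norm(np.asarray(centers) - pos, axis=1)
            if np.all(d > radii[: len(centers)] + r + 1.0):
                centers.append(pos)
                break
        else:
            raise RuntimeError(
                "could not place non-overlapping nuclei; lower n_nuclei "
                "or the radius"
            )
    return np.asarray(centers)


def _render_disks(shape: tuple[int, int], centers: np.ndarray,
                  radii: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return (coverage in [0,1], binary mask) for a union of disks.

    Coverage is anti-aliased with a 1-px linear edge ramp; the mask is
    the exact rasterization ``dist <= r``.
    """
    coverage = np.zeros(shape, dtype=float)
    mask = np.zeros(shape, dtype=bool)
    h, w = shape
    for (cy, cx), r in zip(centers, radii):
        y0, y1 = int(max(0, np.floor(cy - r - 2))), int(min(h, np.ceil(cy + r + 3)))
        x0, x1 = int(max(0, np.floor(cx - r - 2))), int(min(w, np.ceil(cx + r + 3)))
        yy, xx = np.mgrid[y0:y1, x0:x1]
        dist = np.hypot(yy - cy, xx - cx)
        cov = np.clip(r + 0.5 - dist, 0.0, 1.0)
        coverage[y0:y1, x0:x1] = np.maximum(coverage[y0:y1, x0:x1], cov)
        mask[y0:y1, x0:x1] |= dist <= r
    return coverage, mask


def generate_patch(spec: NucleiSceneSpec) -> PatchSample:
    """Render a nuclei scene and return it with its ground truth.

    The returned mask marks exactly the union of the nucleus disks
    (pixels whose center lies within radius of a nucleus center).
    """
    rng = np.random.default_rng(spec.seed)
    shape = (spec.height_px, spec.width_px)

    radii = np.clip(
        rng.normal(spec.radius_px_mean, spec.radius_px_sd, spec.n_nuclei),
        2.0, None,
    )
    centers = _sample_centers(spec, radii, rng)
    coverage, mask = _render_disks(shape, centers, radii)

    if spec.grayscale:
        img = spec.background_level + coverage * (
            spec.nucleus_level - spec.background_level
        )
        img = img + rng.normal(0.0, spec.noise_sd, shape)
        image = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    else:
        scale_bg = spec.background_level / 220.0
        scale_nu = spec.nucleus_level / 70.0
        base = np.clip(_TISSUE_RGB * scale_bg, 0, 255)
        dark = np.clip(_NUCLEUS_RGB * scale_nu, 0, 255)
        img = base[None, None, :] + coverage[..., None] * (dark - base)
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)
        image = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return PatchSample(image=image, centers=centers, radii=radii, mask=mask)


def generate_wsi(
    tissue_fraction: float,
    spec: NucleiSceneSpec,
) -> tuple[np.ndarray, np.ndarray]:
    """Render a slide-sized raster with a known tissue mask.

    The tissue region is the super-level set of a smoothed Gaussian
    random field thresholded at the requested quantile, so the true mask
    covers ``tissue_fraction`` of the pixels up to rasterization ties.
    Nuclei are placed only inside tissue; the background is near-white.
    Returns ``(image, true_mask)``.
    """
    if not 0.0 <= tissue_fraction <= 1.0:
        raise ValueError("tissue_fraction must be in [0, 1]")
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height_px, spec.width_px
    shape = (h, w)

    if tissue_fraction == 0.0:
        mask = np.zeros(shape, dtype=bool)
    elif tissue_fraction == 1.0:
        mask = np.ones(shape, dtype=bool)
    else:
        blob = ndi.gaussian_filter(rng.standard_normal(shape), sigma=min(h, w) / 8)
        thresh = np.quantile(blob, 1.0 - tissue_fraction)
        mask = blob > thresh

    # nuclei only where there is tissue
    coverage = np.zeros(shape, dtype=float)
    n_tissue = int(mask.sum())
    if n_tissue > 0 and spec.n_nuclei > 0:
        flat = np.flatnonzero(mask)
        radii = np.clip(
            rng.normal(spec.radius_px_mean, spec.radius_px_sd, spec.n_nuclei),
            2.0, None,
        )
        picks = flat[rng.integers(0, flat.size, spec.n_nuclei)]
        centers = np.column_stack(np.unravel_index(picks, shape)).astype(float)
        coverage, _ = _render_disks(shape, centers, radii)

    img = np.where(
        mask[..., None], _TISSUE_RGB[None, None, :], _BACKGROUND_RGB[None, None, :]
    )
    dark = _NUCLEUS_RGB[None, None, :]
    img = img + coverage[..., None] * (dark - img)
    img = img + rng.normal(0.0, spec.noise_sd, img.shape)
    image = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return image, mask


# ---------------------------------------------------------------------------
# feature cohorts
# ---------------------------------------------------------------------------


def generate_cohort(
    spec: CohortSpec,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw a feature matrix with a planted discriminative subset.

    Returns ``(X, y, informative_idx)`` where ``X`` is n_samples ×
    n_features, ``y`` is binary with fixed class counts
    ``round(n·class_balance)`` positives, and the informative columns are
    shifted by ``effect_size`` (in SD units) in the positive class.
    """
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_samples, spec.n_features

    n_pos = int(round(n * spec.class_balance))
    n_pos = min(max(n_pos, 1), n - 1)  # both classes present
    y = np.zeros(n, dtype=int)
    y[:n_pos] = 1
    y = rng.permutation(y)

    X = rng.standard_normal((n, p))

    idx = rng.permutation(p)
    informative = np.sort(idx[: spec.n_informative])

    if spec.correlated_block_rho > 0.0:
        # Pearson r chosen so the expected Spearman rho matches the request
        r = min(2.0 * np.sin(np.pi * spec.correlated_block_rho / 6.0), 0.999)
        noise_cols = np.sort(idx[spec.n_informative:])
        block = noise_cols[: min(10, noise_cols.size)]
        if block.size >= 2:
            shared = rng.standard_normal(n)
            X[:, block] = (
                np.sqrt(r) * shared[:, None]
                + np.sqrt(1.0 - r) * rng.standard_normal((n, block.size))
            )

    X[np.ix_(y == 1, informative)] += spec.effect_size
    return X, y, informative


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------


def make_gene_sets(
    n_genes: int,
    n_sets: int,
    set_size: int,
    seed: int = 0,
) -> dict[str, list[str]]:
    """Draw disjoint random gene sets over the gene universe."""
    if n_sets * set_size > n_genes:
        raise ValueError("gene sets do not fit disjointly in the universe")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_genes)
    return {
        f"SET_{s:02d}": [gene_id(i) for i in order[s * set_size:(s + 1) * set_size]]
        for s in range(n_sets)
    }


def generate_expression(
    spec: ExpressionSpec,
    group_labels: np.ndarray,
) -> pd.DataFrame:
    """Draw a gene × sample log-expression matrix with planted sets.

    ``group_labels`` assigns each sample to the "high" (1/"high") or
    "low" (0/"low") pathomic-score group.  Genes in planted up-sets are
    shifted up by ``effect_size`` SDs in the high group, down-sets down;
    all other genes are null.
    """
    groups = np.asarray(group_labels)
    high = (groups == 1) | (groups == "high")
    low = (groups == 0) | (groups == "low")
    if not (high.any() and low.any()):
        raise ValueError("group_labels must contain both groups")
    if groups.shape[0] != spec.n_samples:
        raise ValueError("group_labels length must equal n_samples")

    rng = np.random.default_rng(spec.seed)
    genes = [gene_id(i) for i in range(spec.n_genes)]
    samples = [f"s{j:03d}" for j in range(spec.n_samples)]
    E = rng.standard_normal((spec.n_genes, spec.n_samples))

    index = {g: i for i, g in enumerate(genes)}
    for name in spec.planted_up_sets:
        rows = [index[g] for g in spec.gene_sets[name]]
        E[np.ix_(rows, np.flatnonzero(high))] += spec.effect_size
    for name in spec.planted_down_sets:
        rows = [index[g] for g in spec.gene_sets[name]]
        E[np.ix_(rows, np.flatnonzero(high))] -= spec.effect_size

    return pd.DataFrame(E, index=genes, columns=samples)
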