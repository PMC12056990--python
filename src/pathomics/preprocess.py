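"""Tissue masking and nuclei-aware patch extraction.

A slide enters the pipeline as a flat RGB (or grayscale) raster.  The
tissue mask is built by grayscale conversion, Otsu thresholding (tissue
is the darker side), binary dilation, hole filling and small-object
removal; slides are gated on a minimum tissue fraction (default 80%).
Accepted slides are tiled into fixed-size patches (default 2000 px,
non-overlapping) and each patch is scored by its nuclei pixel coverage;
patches below the coverage threshold (default 15%) are rejected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.color import rgb2gray
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_holes, remove_small_objects

from .nuclei import segment_nuclei

__all__ = [
    "TissueMask",
    "PatchRecord",
    "tissue_mask",
    "passes_tissue_gate",
    "extract_patches",
    "nuclei_coverage_score",
    "to_gray",
]

DEFAULT_TISSUE_THRESHOLD = 0.80
DEFAULT_COVERAGE_THRESHOLD = 0.15
DEFAULT_PATCH_PX = 2000


@dataclass
class TissueMask:
    """Binary tissue mask aligned to its source raster."""

    mask: np.ndarray

    @property
    def tissue_fraction(self) -> float:
        return float(self.mask.mean()) if self.mask.size else 0.0


@dataclass
class PatchRecord:
    """One extracted patch with its grid origin and nuclei score."""

    image: np.ndarray
    x: int  # column of the top-left corner, 0-based
    y: int  # row of the top-left corner, 0-based
    nuclei_coverage: float | None = None
    accepted: bool | None = None
    slide_id: str | None = field(default=None)


def to_gray(image: np.ndarray) -> np.ndarray:
    """Convert a 2-D or 3-channel raster to float grayscale in [0, 1]."""
    arr = np.asarray(image)
    if arr.ndim == 3:
        return rgb2gray(arr[..., :3])
    if arr.ndim != 2:
        raise ValueError("expected a 2-D or 3-channel raster")
    g = arr.astype(float)
    if arr.dtype == np.uint8:
        g = g / 255.0
    return g


def tissue_mask(
    image: np.ndarray,
    dilation_footprint: int = 3,
    hole_area_px: int = 64,
    min_object_px: int = 64,
) -> TissueMask:
    """Segment tissue from background.

    Pipeline: grayscale → Otsu threshold (tissue = darker side) → binary
    dilation (``dilation_footprint``² square) → fill holes below
    ``hole_area_px`` → drop connected components below ``min_object_px``.
    A constant image (Otsu undefined) yields an empty mask with a warning.
    """
    gray = to_gray(image)
    if gray.size == 0:
        raise ValueError("empty raster")
    if np.ptp(gray) == 0:
        warnings.warn("constant image: Otsu threshold undefined, empty tissue mask",
                      stacklevel=2)
        return TissueMask(np.zeros(gray.shape, dtype=bool))

    t = threshold_otsu(gray)
    mask = gray < t
    mask = ndi.binary_dilation(
        mask, structure=np.ones((dilation_footprint, dilation_footprint), bool)
    )
    mask = remove_small_holes(mask, max_size=hole_area_px)
    mask = remove_small_objects(mask, max_size=min_object_px)
    return TissueMask(mask)


def passes_tissue_gate(mask: TissueMask, threshold: float = DEFAULT_TISSUE_THRESHOLD) -> bool:
    """True iff the slide's tissue fraction is at least ``threshold``."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    return mask.tissue_fraction >= threshold


def extract_patches(
    image: np.ndarray,
    mask: TissueMask,
    patch_px: int = DEFAULT_PATCH_PX,
    stride_px: int | None = None,
    min_tissue_footprint: float = 0.5,
    slide_id: str | None = None,
) -> list[PatchRecord]:
    """Tile the slide into a non-overlapping patch grid.

    Grid origins run over ``floor(W/stride) × floor(H/stride)`` positions
    (patches always lie fully inside the raster); a patch is kept only if
    at least ``min_tissue_footprint`` of its pixels are tissue.  Coverage
    is left unscored (see :func:`nuclei_coverage_score`).
    """
    if stride_px is None:
        stride_px = patch_px
    arr = np.asarray(image)
    h, w = arr.shape[:2]
    if mask.mask.shape != (h, w):
        raise ValueError("mask does not match image dimensions")
    if patch_px > h or patch_px > w:
        warnings.warn("image smaller than patch size: no patches extracted",
                      stacklevel=2)
        return []

    records = []
    for y in range(0, h - patch_px + 1, stride_px):
        for x in range(0, w - patch_px + 1, stride_px):
            footprint = mask.mask[y:y + patch_px, x:x + patch_px].mean()
            if footprint >= min_tissue_footprint:
                records.append(
                    PatchRecord(image=arr[y:y + patch_px, x:x + patch_px],
                                x=x, y=y, slide_id=slide_id)
                )
    return records


def nuclei_coverage_score(
    patch: PatchRecord | np.ndarray,
    threshold: float = DEFAULT_COVERAGE_THRESHOLD,
) -> tuple[float, bool]:
    """Fraction of patch pixels segmented as nuclei, and the accept flag.

    The same watershed segmentation that later builds density maps is
    used for scoring, so patch selection and density estimation agree on
    what counts as a nucleus.
    """
    arr = patch.image if isinstance(patch, PatchRecord) else np.asarray(patch)
    seg = segment_nuclei(arr)
    score = float((seg.labels > 0).mean()) if seg.labels.size else 0.0
    accepted = score >= threshold
    if isinstance(patch, PatchRecord):
        patch.nuclei_coverage = score
        patch.accepted = accepted
    return score, accepted
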