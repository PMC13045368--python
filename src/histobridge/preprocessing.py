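"""Slide-to-patch front end and IHC stain quantification.

Tissue is separated from the bright slide background by Otsu thresholding
of the Gaussian-blurred HSV saturation channel; the tissue area is then
covered with sliding-window patches, each patch keeping its tissue
fraction.  Patches can be triaged into positive/negative sets by their
cosine similarity to user-supplied anchor features.  DAB positivity of an
IHC patch is quantified by optical-density color deconvolution with the
Ruifrok-Johnston hematoxylin-DAB stain matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.color import hdx_from_rgb, rgb2hsv, separate_stains
from skimage.filters import threshold_otsu

__all__ = ["TissueMask", "PatchRecord", "tissue_mask", "tile_patches",
           "extract_patch", "triage_patches", "dab_positivity"]


@dataclass(frozen=True)
class TissueMask:
    mask: np.ndarray
    source_shape: tuple[int, int]

    def __post_init__(self):
        if self.mask.shape != self.source_shape:
            raise ValueError("mask shape must equal source image plane shape")


@dataclass(frozen=True)
class PatchRecord:
    """Half-open window [x, x+size) x [y, y+size), 0-based pixel coordinates."""
    x: int
    y: int
    size: int
    tissue_fraction: float
    triage_label: str = "unassigned"


def tissue_mask(slide: np.ndarray, blur_sigma: float = 5.0) -> TissueMask:
    """Otsu threshold on the Gaussian-blurred saturation channel.

    Above-threshold (saturated) pixels are tissue.  A slide with constant
    saturation has no Otsu split; it yields an empty mask with a warning.
    """
    slide = np.asarray(slide, dtype=np.float64)
    if slide.ndim != 3 or slide.shape[2] != 3 or slide.size == 0:
        raise ValueError(f"expected a nonempty HxWx3 RGB slide, got {slide.shape}")
    sat = rgb2hsv(slide)[..., 1]
    blurred = gaussian_filter(sat, sigma=blur_sigma)
    if np.ptp(blurred) < 1e-6:
        warnings.warn("saturation channel is constant; returning empty tissue mask",
                      stacklevel=2)
        mask = np.zeros(blurred.shape, dtype=bool)
    else:
        mask = blurred > threshold_otsu(blurred)
    return TissueMask(mask=mask, source_shape=blurred.shape)


def tile_patches(slide: np.ndarray, mask: TissueMask, patch_size: int,
                 stride: int, min_tissue_fraction: float = 0.5,
                 ) -> list[PatchRecord]:
    """Sliding-window patch records over the tissue mask, row-major order.

    Windows lie fully inside the image; a record is kept when its tissue
    fraction is at least ``min_tissue_fraction``.
    """
    h, w = mask.source_shape
    if patch_size > h or patch_size > w:
        raise ValueError(f"patch_size {patch_size} exceeds image dims {(h, w)}")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    # integral image for O(1) per-window tissue sums
    integral = np.zeros((h + 1, w + 1), dtype=np.int64)
    integral[1:, 1:] = np.cumsum(np.cumsum(mask.mask.astype(np.int64), axis=0), axis=1)
    records = []
    area = patch_size * patch_size
    for y in range(0, h - patch_size + 1, stride):
        for x in range(0, w - patch_size + 1, stride):
            s = (integral[y + patch_size, x + patch_size] - integral[y, x + patch_size]
                 - integral[y + patch_size, x] + integral[y, x])
            frac = s / area
            if frac >= min_tissue_fraction:
                records.append(PatchRecord(x=x, y=y, size=patch_size,
                                           tissue_fraction=float(frac)))
    return records


def extract_patch(slide: np.ndarray, record: PatchRecord) -> np.ndarray:
    return np.asarray(slide)[record.y:record.y + record.size,
                             record.x:record.x + record.size]


def triage_patches(patch_features: np.ndarray, positive_anchors: np.ndarray,
                   negative_anchors: np.ndarray) -> list[str]:
    """Label each patch by its closest anchor set under cosine similarity.

    A patch is positive iff its maximum similarity to the positive anchors
    strictly exceeds that to the negative anchors (ties go negative).
    """
    f = np.asarray(patch_features, dtype=np.float64)
    pos = np.asarray(positive_anchors, dtype=np.float64)
    neg = np.asarray(negative_anchors, dtype=np.float64)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("anchor sets must be nonempty")
    if f.shape[1] != pos.shape[1] or f.shape[1] != neg.shape[1]:
        raise ValueError("feature dimension mismatch between patches and anchors")

    def _sims(a, b):
        an = a / np.linalg.norm(a, axis=1, keepdims=True)
        bn = b / np.linalg.norm(b, axis=1, keepdims=True)
        return an @ bn.T

    best_pos = _sims(f, pos).max(axis=1)
    best_neg = _sims(f, neg).max(axis=1)
    return ["positive" if p > n else "negative" for p, n in zip(best_pos, best_neg)]


def dab_positivity(patch: np.ndarray) -> float:
    """Mean DAB-channel stain concentration after H-DAB color deconvolution.

    The RGB patch (values in [0, 1]) is converted to optical density (with
    the usual small-intensity clamp) and unmixed with the Ruifrok-Johnston
    hematoxylin-DAB matrix; the mean of the DAB channel, floored at zero, is
    the positivity score.  A pure-white patch scores ~0.
    """
    patch = np.asarray(patch, dtype=np.float64)
    if patch.ndim != 3 or patch.shape[2] != 3:
        raise ValueError(f"expected HxWx3 RGB patch, got shape {patch.shape}")
    if patch.min() < 0 or patch.max() > 1:
        raise ValueError("patch values must lie in [0, 1]")
    stains = separate_stains(patch, hdx_from_rgb)  # channels: H, DAB, residual
    return float(np.clip(stains[..., 1], 0.0, None).mean())
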