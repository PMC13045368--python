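"""Image feature extractors feeding the FID/retrieval/inlier metrics.

The metrics are defined over any fixed-length feature map, so the extractor
is a pluggable contract.  The default extractor is a deterministic
random-projection pipeline: images are resized to a fixed grid by block
averaging, centred, passed through a fixed-seed Gaussian projection and a
tanh nonlinearity, and augmented with per-channel moment statistics.  It
carries no learned weights, is identical across runs by construction, and
preserves the ordinal structure (hue, brightness, texture contrasts) that
the relative metrics in this package rely on.  Reproducing absolute FID
magnitudes from pretrained deep networks is out of scope by design.
"""

from __future__ import annotations

from typing import Callable, Protocol

import numpy as np

__all__ = ["FeatureExtractor", "RandomProjectionExtractor", "extract_features"]


class FeatureExtractor(Protocol):
    name: str

    def __call__(self, image: np.ndarray) -> np.ndarray:
        """Map one HxWx3 image in [0, 1] to a fixed-length feature vector."""
        ...


def _block_resize(img: np.ndarray, size: int) -> np.ndarray:
    """Average-pool an HxWxC image onto a size x size grid (H, W multiples ok)."""
    h, w = img.shape[:2]
    ys = (np.arange(size + 1) * h) // size
    xs = (np.arange(size + 1) * w) // size
    out = np.empty((size, size, img.shape[2]), dtype=np.float64)
    for i in range(size):
        for j in range(size):
            out[i, j] = img[ys[i]:ys[i + 1], xs[j]:xs[j + 1]].mean(axis=(0, 1))
    return out


class RandomProjectionExtractor:
    """Fixed-seed tanh(W x + b) features plus channel moment summaries.

    Parameters
    ----------
    dim : output feature length (projection part); 8 moment features are
        appended, so vectors have length ``dim + 8``.
    grid : spatial resolution the image is block-averaged onto first.
    seed : seed of the fixed projection; part of the metric definition, not
        of experiment randomness.
    """

    def __init__(self, dim: int = 120, grid: int = 16, seed: int = 7_771):
        rng = np.random.default_rng(seed)
        n_in = grid * grid * 3
        self.w = rng.standard_normal((n_in, dim)) / np.sqrt(n_in)
        self.b = rng.standard_normal(dim) * 0.1
        self.grid = grid
        self.dim = dim
        self.name = f"random-projection-{dim}@{grid}"

    def __call__(self, image: np.ndarray) -> np.ndarray:
        img = np.asarray(image, dtype=np.float64)
        if img.ndim != 3 or img.shape[2] != 3:
            raise ValueError(f"expected HxWx3 image, got shape {img.shape}")
        small = _block_resize(img, self.grid)
        z = small.reshape(-1) - 0.5
        proj = np.tanh(4.0 * (z @ self.w) + self.b)
        mom = np.concatenate([small.mean(axis=(0, 1)) - 0.5,
                              small.std(axis=(0, 1)),
                              [small.max() - small.min(),
                               float(np.abs(np.diff(small, axis=0)).mean())]])
        return np.concatenate([proj, mom])


def extract_features(images: np.ndarray,
                     extractor: FeatureExtractor | Callable[[np.ndarray], np.ndarray] | None = None,
                     ) -> np.ndarray:
    """Stack extractor outputs for a BxHxWx3 image array into an n x d matrix."""
    if extractor is None:
        extractor = RandomProjectionExtractor()
    images = np.asarray(images)
    if images.ndim == 3:
        images = images[None]
    return np.stack([np.asarray(extractor(im), dtype=np.float64) for im in images])
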