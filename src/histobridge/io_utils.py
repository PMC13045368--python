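"""Image I/O and value-range conversions.

Model I/O uses float images in [-1, 1]; files store 8-bit RGB (PNG or
TIFF).  The conversions round-trip losslessly up to the 1/255 quantization.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

__all__ = ["to_model_range", "from_model_range", "to_unit_range", "load_image",
           "save_image"]


def to_model_range(img01: np.ndarray) -> np.ndarray:
    """[0, 1] floats -> [-1, 1] floats."""
    return np.asarray(img01, dtype=np.float32) * 2.0 - 1.0


def from_model_range(img: np.ndarray) -> np.ndarray:
    """[-1, 1] floats -> [0, 1] floats, clipped."""
    return np.clip((np.asarray(img, dtype=np.float32) + 1.0) / 2.0, 0.0, 1.0)


def to_unit_range(img_u8: np.ndarray) -> np.ndarray:
    """8-bit RGB -> [0, 1] floats."""
    return np.asarray(img_u8, dtype=np.float32) / 255.0


def load_image(path) -> np.ndarray:
    """Read a PNG/TIFF image as HxWx3 floats in [0, 1]."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path).convert("RGB"))
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.dtype != np.uint8:
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    return to_unit_range(arr[..., :3])


def save_image(path, img01: np.ndarray) -> None:
    """Write HxWx3 floats in [0, 1] as 8-bit PNG or TIFF (by extension)."""
    path = Path(path)
    u8 = np.clip(np.round(np.asarray(img01) * 255.0), 0, 255).astype(np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, u8)
    else:
        Image.fromarray(u8).save(path)
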