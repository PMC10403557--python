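"""Shared image helpers: validation and 8-bit quantization."""

from __future__ import annotations

import numpy as np


def quantize_u8(arr: np.ndarray) -> np.ndarray:
    """Quantize a real-valued raster to 8 bits.

    Values are clipped to [0, 255] and rounded half-away-from-zero (for
    nonnegative values, ``floor(x + 0.5)``).  The rounding rule is fixed so
    that transform outputs are bit-exact across platforms.
    """
    arr = np.asarray(arr, dtype=np.float64)
    return np.clip(np.floor(arr + 0.5), 0, 255).astype(np.uint8)


def as_float(image: np.ndarray) -> np.ndarray:
    """Validate an 8-bit grayscale image and return a float64 working copy."""
    img = np.asarray(image)
    if img.ndim != 2 or img.shape[0] < 1 or img.shape[1] < 1:
        raise ValueError(f"expected a 2D grayscale image, got shape {img.shape}")
    if img.dtype != np.uint8:
        arr = np.asarray(img, dtype=np.float64)
        if np.any(arr < 0) or np.any(arr > 255):
            raise ValueError("image values must lie in [0, 255]")
        return arr
    return img.astype(np.float64)
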