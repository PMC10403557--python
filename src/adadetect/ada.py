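"""Acquisition-dependent attribute (ADA) transforms.

Two global image attributes are modeled, each with a canonical one-parameter
operator:

* **contrast** — a power-law (gamma) intensity mapping
  ``out = 255 * (in / 255) ** gamma``; ``gamma > 1`` darkens midtones
  (higher apparent contrast in the bright body field), ``gamma < 1`` lifts
  them, ``gamma = 1`` is the identity.
* **sharpness** — Gaussian smoothing (softening, ``blur_sigma`` pixels) or an
  unsharp mask (sharpening, gain ``sharpen_amount`` over a fixed internal
  smoothing scale of 1.0 px).

These are the perturbations injected into one class of a shortcut-detective
training set, and the perturbations a certified detective is later trusted to
recognize in the wild.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ._image import as_float, quantize_u8

#: internal smoothing scale of the unsharp mask, in pixels
UNSHARP_SIGMA = 1.0


@dataclass(frozen=True)
class ADASpec:
    """Parameterized description of one acquisition-dependent perturbation.

    Exactly one attribute family is active: for ``attribute="contrast"`` only
    ``gamma`` may differ from its identity value; for ``attribute="sharpness"``
    at most one of ``blur_sigma`` (softening) and ``sharpen_amount``
    (sharpening) is nonzero.
    """

    attribute: str
    gamma: float = 1.0
    blur_sigma: float = 0.0
    sharpen_amount: float = 0.0

    def __post_init__(self) -> None:
        if self.attribute not in ("contrast", "sharpness"):
            raise ValueError(
                f"attribute must be 'contrast' or 'sharpness', got {self.attribute!r}"
            )
        if self.gamma <= 0:
            raise ValueError(f"gamma must be positive, got {self.gamma}")
        if self.blur_sigma < 0:
            raise ValueError(f"blur_sigma must be nonnegative, got {self.blur_sigma}")
        if self.sharpen_amount < 0:
            raise ValueError(
                f"sharpen_amount must be nonnegative, got {self.sharpen_amount}"
            )
        if self.attribute == "contrast" and (self.blur_sigma or self.sharpen_amount):
            raise ValueError("contrast spec must have blur_sigma=0 and sharpen_amount=0")
        if self.attribute == "sharpness" and self.gamma != 1.0:
            raise ValueError("sharpness spec must have gamma=1")
        if self.blur_sigma > 0 and self.sharpen_amount > 0:
            raise ValueError("at most one of blur_sigma and sharpen_amount may be nonzero")

    @property
    def is_identity(self) -> bool:
        return self.gamma == 1.0 and self.blur_sigma == 0.0 and self.sharpen_amount == 0.0

    def describe(self) -> str:
        if self.attribute == "contrast":
            return f"contrast(gamma={self.gamma:g})"
        if self.blur_sigma > 0:
            return f"sharpness(blur_sigma={self.blur_sigma:g})"
        if self.sharpen_amount > 0:
            return f"sharpness(sharpen_amount={self.sharpen_amount:g})"
        return "sharpness(identity)"

    def to_dict(self) -> dict:
        return {
            "attribute": self.attribute,
            "gamma": self.gamma,
            "blur_sigma": self.blur_sigma,
            "sharpen_amount": self.sharpen_amount,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ADASpec":
        return cls(
            attribute=d["attribute"],
            gamma=float(d.get("gamma", 1.0)),
            blur_sigma=float(d.get("blur_sigma", 0.0)),
            sharpen_amount=float(d.get("sharpen_amount", 0.0)),
        )


def apply_contrast(image: np.ndarray, gamma: float) -> np.ndarray:
    """Apply a global power-law contrast mapping.

    Each pixel ``p`` maps to ``255 * (p / 255) ** gamma`` in real arithmetic,
    then rounds half-away-from-zero to 8 bits.  The mapping is monotone, fixes
    0 and 255, and ``gamma=1`` is bit-exact identity.
    """
    if gamma <= 0:
        raise ValueError(f"gamma must be positive, got {gamma}")
    img = as_float(image)
    if gamma == 1.0:
        return quantize_u8(img)
    out = 255.0 * np.power(img / 255.0, gamma)
    return quantize_u8(out)


def apply_sharpness(
    image: np.ndarray, blur_sigma: float = 0.0, sharpen_amount: float = 0.0
) -> np.ndarray:
    """Soften (Gaussian blur) or sharpen (unsharp mask) an image.

    ``blur_sigma > 0`` convolves with a normalized Gaussian kernel using
    reflective boundary handling.  ``sharpen_amount > 0`` applies
    ``out = in + amount * (in - Gaussian(in, sigma0))`` with the fixed internal
    scale ``sigma0 =`` :data:`UNSHARP_SIGMA`.  At most one of the two may be
    nonzero; both zero is a bit-exact no-op.
    """
    if blur_sigma < 0 or sharpen_amount < 0:
        raise ValueError("blur_sigma and sharpen_amount must be nonnegative")
    if blur_sigma > 0 and sharpen_amount > 0:
        raise ValueError("at most one of blur_sigma and sharpen_amount may be nonzero")
    img = as_float(image)
    if blur_sigma == 0 and sharpen_amount == 0:
        return quantize_u8(img)
    if blur_sigma > 0:
        out = ndimage.gaussian_filter(img, sigma=blur_sigma, mode="reflect")
    else:
        smooth = ndimage.gaussian_filter(img, sigma=UNSHARP_SIGMA, mode="reflect")
        out = img + sharpen_amount * (img - smooth)
    return quantize_u8(out)


def apply_ada(image: np.ndarray, spec: ADASpec) -> np.ndarray:
    """Apply one acquisition-dependent perturbation per its spec.

    Pure function of ``(image, spec)``; dispatches to :func:`apply_contrast`
    or :func:`apply_sharpness`.
    """
    if not isinstance(spec, ADASpec):
        raise TypeError(f"expected an ADASpec, got {type(spec).__name__}")
    if spec.attribute == "contrast":
        return apply_contrast(image, spec.gamma)
    return apply_sharpness(image, spec.blur_sigma, spec.sharpen_amount)


def gradient_energy(image: np.ndarray) -> float:
    """Mean squared gradient magnitude — the sharpness summary used throughout.

    Blur strictly decreases this on any non-constant image; unsharp masking
    increases it.
    """
    img = as_float(image)
    gy, gx = np.gradient(img)
    return float(np.mean(gx * gx + gy * gy))
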