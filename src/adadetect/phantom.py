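"""Procedural frontal-radiograph phantom generator.

Emulates the gross structure of a frontal chest radiograph: a bright elliptical
body field on a dark background, two darker lung ellipses at mirrored
horizontal offsets, sinusoidal rib bands across the lung fields, additive
Gaussian detector noise, and — crucially — per-image *baseline* gamma and blur
draws applied to every image regardless of label.  The baseline jitter models
natural acquisition variation, so a shortcut detective must learn the injected
attribute shift rather than memorize absolute contrast or sharpness values.

Labels in :func:`generate_labeled_dataset` are fair coin flips independent of
image content, making the dataset shortcut-free by construction: the
class-conditional distribution of any image statistic is exchangeable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ._image import quantize_u8
from .datasets import LabeledDataset

#: background (air) gray level outside the body ellipse
_BACKGROUND = 25.0


@dataclass(frozen=True)
class PhantomSpec:
    """Controls for the synthetic radiograph generator.

    Parameters
    ----------
    height, width : int
        Image size in pixels.
    body_intensity : float
        Mean gray level of the body field (soft tissue + mediastinum).
    lung_intensity : float
        Mean gray level inside the lung ellipses; must be below
        ``body_intensity`` (lungs are radiolucent).
    rib_count : int
        Number of sinusoidal rib bands crossing each lung field.
    rib_amplitude : float
        Peak rib brightness above the lung level, in gray levels.
    noise_sd : float
        Standard deviation of additive Gaussian noise, gray levels.
    anatomy_jitter : float
        Fractional per-image variation of ellipse axes and centers.
    baseline_gamma_range : (float, float)
        Per-image random gamma applied to every image regardless of label.
    baseline_blur_range : (float, float)
        Per-image random Gaussian sigma (pixels) applied to every image.
    """

    height: int = 64
    width: int = 64
    body_intensity: float = 180.0
    lung_intensity: float = 80.0
    rib_count: int = 4
    rib_amplitude: float = 20.0
    noise_sd: float = 5.0
    anatomy_jitter: float = 0.05
    baseline_gamma_range: tuple[float, float] = (0.95, 1.05)
    baseline_blur_range: tuple[float, float] = (0.0, 0.5)

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("height and width must be >= 1")
        if not (0 <= self.lung_intensity < self.body_intensity <= 255):
            raise ValueError(
                "require 0 <= lung_intensity < body_intensity <= 255, got "
                f"lung_intensity={self.lung_intensity}, body_intensity={self.body_intensity}"
            )
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.rib_count < 0:
            raise ValueError(f"rib_count must be >= 0, got {self.rib_count}")
        if self.rib_amplitude < 0:
            raise ValueError(f"rib_amplitude must be >= 0, got {self.rib_amplitude}")
        if self.anatomy_jitter < 0:
            raise ValueError(f"anatomy_jitter must be >= 0, got {self.anatomy_jitter}")
        for name in ("baseline_gamma_range", "baseline_blur_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must have lower <= upper, got ({lo}, {hi})")
        glo, _ = self.baseline_gamma_range
        if glo <= 0:
            raise ValueError("baseline_gamma_range values must be positive")
        blo, _ = self.baseline_blur_range
        if blo < 0:
            raise ValueError("baseline_blur_range values must be nonnegative")


def _ellipse_mask(
    h: int, w: int, cy: float, cx: float, ay: float, ax: float
) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    return ((yy - cy) / max(ay, 1e-9)) ** 2 + ((xx - cx) / max(ax, 1e-9)) ** 2 <= 1.0


def _anatomy_masks(
    spec: PhantomSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Body and lung masks with per-image jitter on centers and axes."""
    h, w, j = spec.height, spec.width, spec.anatomy_jitter

    def jit() -> float:
        return float(rng.uniform(-j, j))

    body = _ellipse_mask(
        h, w,
        cy=h * (0.52 + 0.5 * jit()),
        cx=w * (0.50 + 0.5 * jit()),
        ay=h * 0.46 * (1 + jit()),
        ax=w * 0.40 * (1 + jit()),
    )
    lungs = np.zeros((h, w), dtype=bool)
    for side in (-1.0, 1.0):
        lungs |= _ellipse_mask(
            h, w,
            cy=h * (0.45 + 0.5 * jit()),
            cx=w * (0.50 + side * 0.20 * (1 + jit())),
            ay=h * 0.27 * (1 + jit()),
            ax=w * 0.13 * (1 + jit()),
        )
    lungs &= body
    return body, lungs


def generate_phantom(spec: PhantomSpec, seed: int) -> np.ndarray:
    """Generate one synthetic frontal-radiograph-like 8-bit image.

    Deterministic given ``(spec, seed)``.  With all randomness disabled
    (``noise_sd=0``, ``anatomy_jitter=0``, degenerate baseline ranges) the
    output is independent of the seed.
    """
    rng = np.random.default_rng(seed)
    h, w = spec.height, spec.width

    body, lungs = _anatomy_masks(spec, rng)
    img = np.full((h, w), _BACKGROUND, dtype=np.float64)
    img[body] = spec.body_intensity
    img[lungs] = spec.lung_intensity

    if spec.rib_count > 0 and lungs.any():
        phase = float(rng.uniform(0, 2 * np.pi)) if spec.anatomy_jitter > 0 else 0.0
        yy = np.arange(h, dtype=np.float64)[:, None]
        ribs = 0.5 * spec.rib_amplitude * (
            1 + np.sin(2 * np.pi * spec.rib_count * yy / h + phase)
        )
        img = np.where(lungs, img + ribs, img)

    img += rng.normal(0.0, spec.noise_sd, size=(h, w))
    img = np.clip(img, 0, 255)

    # baseline acquisition jitter: both classes receive it, so only an
    # injected shift — not absolute contrast/sharpness — separates classes
    g = float(rng.uniform(*spec.baseline_gamma_range))
    if g != 1.0:
        img = 255.0 * np.power(img / 255.0, g)
    s = float(rng.uniform(*spec.baseline_blur_range))
    if s > 0:
        img = ndimage.gaussian_filter(img, sigma=s, mode="reflect")

    return quantize_u8(img)


def generate_labeled_dataset(
    n: int, spec: PhantomSpec = PhantomSpec(), seed: int = 0
) -> LabeledDataset:
    """Generate ``n`` phantoms with labels drawn by fair coin.

    Labels are independent of image content, so the dataset carries no
    shortcut by construction.  Each record gets a unique synthetic patient ID.
    Deterministic given ``(n, spec, seed)``.
    """
    if n < 2:
        raise ValueError(f"need n >= 2, got {n}")
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, 2, size=n).astype(np.int64)
    image_seeds = rng.integers(0, 2**31 - 1, size=n)
    images = [generate_phantom(spec, int(s)) for s in image_seeds]
    patient_ids = [f"P{seed:04d}-{i:06d}" for i in range(n)]
    return LabeledDataset(
        images=images,
        labels=labels,
        patient_ids=patient_ids,
        name=f"phantom(n={n},seed={seed})",
    )
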