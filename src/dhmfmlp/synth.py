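"""Synthetic lesion-image generator.

Emulates the kind of data the network targets: grayscale-ish textured
backgrounds with multiplicative speckle (the granular noise characteristic of
ultrasound), containing one to four elliptical "lesions" of varying size —
including a small-lesion regime — with a binary union mask. Every stream is
fully reproducible from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.draw import ellipse as draw_ellipse

from .data import SegmentationSample


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings.

    image_size : square image side in pixels.
    n_images : number of samples to generate.
    lesions_per_image : inclusive (min, max) count of ellipses.
    lesion_radius_fraction : (min, max) semi-major axis as a fraction of the
        image side; the lower end (0.03) is the small-lesion regime.
    eccentricity : (min, max) minor/major axis ratio.
    contrast : intensity offset of lesion interiors above the background.
    texture_amplitude : amplitude of the low-frequency background texture.
    speckle_noise_sd : std of the multiplicative speckle field.
    """

    image_size: int = 256
    n_images: int = 20
    lesions_per_image: tuple[int, int] = (1, 4)
    lesion_radius_fraction: tuple[float, float] = (0.03, 0.25)
    eccentricity: tuple[float, float] = (0.5, 1.0)
    background_level: float = 0.35
    contrast: float = 0.3
    texture_amplitude: float = 0.08
    speckle_noise_sd: float = 0.15
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.lesion_radius_fraction
        if lo <= 0 or hi <= 0:
            raise ValueError("lesion radius fractions must be positive")
        if hi >= 0.5:
            raise ValueError(f"max radius fraction {hi} cannot fit inside the image")
        if self.lesions_per_image[0] < 1:
            raise ValueError("at least one lesion per image is required")


def _background(rng: np.random.Generator, size: int, level: float,
                amplitude: float) -> np.ndarray:
    coarse = rng.normal(0.0, 1.0, size=(max(size // 16, 2),) * 2)
    texture = ndimage.zoom(coarse, size / coarse.shape[0], order=1)[:size, :size]
    return level + amplitude * texture


def _lesion_mask(rng: np.random.Generator, cfg: SynthConfig) -> np.ndarray:
    size = cfg.image_size
    n = int(rng.integers(cfg.lesions_per_image[0], cfg.lesions_per_image[1] + 1))
    mask = np.zeros((size, size), dtype=np.uint8)
    for _ in range(n):
        frac = rng.uniform(*cfg.lesion_radius_fraction)
        r_major = max(frac * size, 1.0)
        r_minor = max(r_major * rng.uniform(*cfg.eccentricity), 1.0)
        margin = int(np.ceil(r_major))
        if 2 * margin >= size:
            raise ValueError(f"lesion radius {r_major:.1f}px too large for a "
                             f"{size}px image")
        cy = rng.uniform(margin, size - margin)
        cx = rng.uniform(margin, size - margin)
        theta = rng.uniform(0, np.pi)
        rr, cc = draw_ellipse(cy, cx, r_major, r_minor, shape=(size, size),
                              rotation=theta)
        mask[rr, cc] = 1
    return mask


def synthesize(cfg: SynthConfig = SynthConfig()) -> list[SegmentationSample]:
    """Generate ``cfg.n_images`` reproducible samples (RGB image + mask)."""
    rng = np.random.default_rng(cfg.seed)
    samples = []
    for i in range(cfg.n_images):
        size = cfg.image_size
        img = _background(rng, size, cfg.background_level, cfg.texture_amplitude)
        mask = _lesion_mask(rng, cfg)
        img = img + cfg.contrast * mask
        img = img * (1.0 + rng.normal(0.0, cfg.speckle_noise_sd, size=img.shape))
        rgb = np.repeat(img[..., None], 3, axis=2)
        rgb = rgb + rng.normal(0.0, 0.01, size=rgb.shape)  # slight channel decorrelation
        rgb = np.clip(rgb, 0.0, 1.0).astype(np.float32)
        samples.append(SegmentationSample(image=rgb, mask=mask,
                                          identifier=f"synthetic_{i:04d}",
                                          provenance="synthetic"))
    return samples
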