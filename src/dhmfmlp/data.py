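"""Dataset I/O, train/test splitting, and lossless augmentation.

Two on-disk layouts are understood:

* ``paired_suffix`` — images and masks side by side, mask files named
  ``<stem>_mask*.<ext>`` (the BUSI convention); several masks for one image
  are merged by pixelwise OR.
* ``two_dirs`` — ``images/`` and ``masks/`` subdirectories with matching
  file names (the ISIC/GlaS convention).

Images are resized bilinearly to the target size; masks are resized with
nearest-neighbour and re-binarized (grayscale masks threshold at 127.5).
Augmentation is restricted to exact, mask-preserving transforms: horizontal
and vertical flips and quarter-turn rotations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

IMAGE_EXTENSIONS = (".png", ".jpg", ".jpeg")


@dataclass
class SegmentationSample:
    """One image/mask pair. ``image`` is float32 RGB (H, W, 3) in [0, 1];
    ``mask`` is uint8 (H, W) with values in {0, 1}."""

    image: np.ndarray
    mask: np.ndarray
    identifier: str
    provenance: str = "disk"

    def __post_init__(self):
        if self.image.shape[:2] != self.mask.shape:
            raise ValueError(f"{self.identifier}: image {self.image.shape[:2]} and "
                             f"mask {self.mask.shape} sizes differ")
        if not np.isin(self.mask, (0, 1)).all():
            raise ValueError(f"{self.identifier}: mask is not binary")


# ------------------------------------------------------------------ file I/O

def _read_image(path: Path, target_size: int | None) -> np.ndarray:
    try:
        with Image.open(path) as im:
            im = im.convert("RGB")
            if target_size is not None and im.size != (target_size, target_size):
                im = im.resize((target_size, target_size), Image.BILINEAR)
            return np.asarray(im, dtype=np.float32) / 255.0
    except OSError as exc:
        raise OSError(f"unreadable image file {path}: {exc}") from exc


def _read_mask(path: Path, target_size: int | None) -> np.ndarray:
    try:
        with Image.open(path) as im:
            im = im.convert("L")
            if target_size is not None and im.size != (target_size, target_size):
                im = im.resize((target_size, target_size), Image.NEAREST)
            return (np.asarray(im, dtype=np.float32) > 127.5).astype(np.uint8)
    except OSError as exc:
        raise OSError(f"unreadable mask file {path}: {exc}") from exc


def _pairs_paired_suffix(root: Path) -> dict[str, tuple[Path, list[Path]]]:
    images: dict[str, Path] = {}
    masks: dict[str, list[Path]] = {}
    for p in sorted(root.rglob("*")):
        if p.suffix.lower() not in IMAGE_EXTENSIONS:
            continue
        stem = p.stem
        if "_mask" in stem:
            base = stem.split("_mask")[0]
            masks.setdefault(base, []).append(p)
        else:
            images[stem] = p
    orphan_imgs = sorted(set(images) - set(masks))
    orphan_masks = sorted(set(masks) - set(images))
    if orphan_imgs or orphan_masks:
        raise ValueError(f"unpaired files under {root}: images without masks "
                         f"{orphan_imgs}, masks without images {orphan_masks}")
    return {k: (images[k], sorted(masks[k])) for k in sorted(images)}


def _pairs_two_dirs(root: Path) -> dict[str, tuple[Path, list[Path]]]:
    img_dir, mask_dir = root / "images", root / "masks"
    if not img_dir.is_dir() or not mask_dir.is_dir():
        raise ValueError(f"{root} must contain images/ and masks/ subdirectories")
    images = {p.stem: p for p in sorted(img_dir.iterdir())
              if p.suffix.lower() in IMAGE_EXTENSIONS}
    masks = {p.stem: p for p in sorted(mask_dir.iterdir())
             if p.suffix.lower() in IMAGE_EXTENSIONS}
    orphan_imgs = sorted(set(images) - set(masks))
    orphan_masks = sorted(set(masks) - set(images))
    if orphan_imgs or orphan_masks:
        raise ValueError(f"unpaired files under {root}: images without masks "
                         f"{orphan_imgs}, masks without images {orphan_masks}")
    return {k: (images[k], [masks[k]]) for k in sorted(images)}


def load_dataset(root, layout: str = "paired_suffix",
                 target_size: int | None = 256) -> list[SegmentationSample]:
    """Load image/mask pairs in deterministic lexicographic order."""
    root = Path(root)
    if layout == "paired_suffix":
        pairs = _pairs_paired_suffix(root)
    elif layout == "two_dirs":
        pairs = _pairs_two_dirs(root)
    else:
        raise ValueError(f"unknown layout {layout!r}; use 'paired_suffix' or 'two_dirs'")
    samples = []
    for ident, (img_path, mask_paths) in pairs.items():
        image = _read_image(img_path, target_size)
        mask = np.zeros(image.shape[:2], dtype=np.uint8)
        for mp in mask_paths:  # multi-mask cases merge by pixelwise OR
            mask |= _read_mask(mp, target_size)
        samples.append(SegmentationSample(image=image, mask=mask, identifier=ident))
    return samples


def save_dataset(samples, out_dir, layout: str = "two_dirs") -> None:
    """Write samples to disk as PNG (masks as {0, 255})."""
    out_dir = Path(out_dir)
    if layout == "two_dirs":
        (out_dir / "images").mkdir(parents=True, exist_ok=True)
        (out_dir / "masks").mkdir(parents=True, exist_ok=True)
        for s in samples:
            _write_png(out_dir / "images" / f"{s.identifier}.png", s.image)
            _write_png(out_dir / "masks" / f"{s.identifier}.png", s.mask * 255)
    elif layout == "paired_suffix":
        out_dir.mkdir(parents=True, exist_ok=True)
        for s in samples:
            _write_png(out_dir / f"{s.identifier}.png", s.image)
            _write_png(out_dir / f"{s.identifier}_mask.png", s.mask * 255)
    else:
        raise ValueError(f"unknown layout {layout!r}")


def _write_png(path: Path, array: np.ndarray) -> None:
    if array.dtype != np.uint8:
        array = np.clip(np.asarray(array, dtype=np.float32) * 255.0, 0, 255
                        ).round().astype(np.uint8)
    Image.fromarray(array).save(path)


def save_mask(path, mask: np.ndarray) -> None:
    """Write a predicted binary mask as a {0, 255} PNG."""
    _write_png(Path(path), np.asarray(mask, dtype=np.uint8) * 255)


# ---------------------------------------------------------------- splitting

def split(samples, ratio: float = 0.8, seed: int = 0):
    """Seeded shuffle then disjoint, exhaustive split; the training share is
    floor(ratio * n)."""
    if not 0 < ratio < 1:
        raise ValueError(f"split ratio must lie in (0,1), got {ratio}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(samples))
    n_train = math.floor(ratio * len(samples))
    train = [samples[i] for i in order[:n_train]]
    test = [samples[i] for i in order[n_train:]]
    return train, test


# --------------------------------------------------------------- augmentation

def augment(sample: SegmentationSample, rng: np.random.Generator) -> SegmentationSample:
    """Independent 50% horizontal flip, 50% vertical flip, and a uniformly
    chosen k*90-degree rotation, applied identically to image and mask."""
    image, mask = sample.image, sample.mask
    if rng.random() < 0.5:
        image, mask = image[:, ::-1], mask[:, ::-1]
    if rng.random() < 0.5:
        image, mask = image[::-1], mask[::-1]
    k = int(rng.integers(0, 4))
    if k:
        image, mask = np.rot90(image, k, axes=(0, 1)), np.rot90(mask, k)
    return SegmentationSample(image=np.ascontiguousarray(image),
                              mask=np.ascontiguousarray(mask),
                              identifier=sample.identifier,
                              provenance=sample.provenance)
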