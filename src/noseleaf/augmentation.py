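"""Image augmentation operators and training-set expansion.

The augmentation stack mirrors the study's recipe: GridMask occlusion,
blacking out every fourth pixel row, additive Gaussian noise, rotating only
the red channel, and Gaussian blur; images are finally resized to 224×224
and channel-standardized for the network.  Every operator is deterministic
given its seed and operates on 8-bit RGB ``(H, W, 3)`` arrays.

Training-set expansion is manifest-driven: an explicit per-class map says
how many augmented copies to add, so any printed dataset accounting can be
reproduced exactly.  Augmented records never derive from test images.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

from .manifest import COLUMNS, DatasetManifest, split_dataset  # noqa: F401 (re-export)

__all__ = [
    "AugmentConfig", "gridmask", "row_blackout", "gaussian_noise",
    "red_channel_rotate", "gaussian_blur", "resize_normalize",
    "dataset_statistics", "augment_training_set", "split_dataset",
    "IMAGENET_MEAN", "IMAGENET_STD",
]

IMAGENET_MEAN = (0.485, 0.456, 0.406)
IMAGENET_STD = (0.229, 0.224, 0.225)

# Per-class augmented-copy counts reproducing the study's final training
# set (final training count minus original training count, per species).
TABLE1_ADDED = {
    "R_affinis": 86, "R_macrotis": 198, "R_nippon": 80, "R_pearsonii": 101,
    "R_pernigei": 107, "R_pusillus": 55, "R_sinicus": 67,
}


@dataclass
class AugmentConfig:
    """Parameters of the augmentation stack.

    ``gridmask_keep_ratio`` is the per-axis kept fraction (kept area is its
    square); unit sizes are drawn uniformly from ``gridmask_unit_range``.
    Sigmas are fractions of the 255 intensity range for noise and pixels
    for blur.  ``per_class_multiplicity`` maps class name to the number of
    augmented copies to add; the default reproduces the published accounting
    for the seven *Rhinolophus* classes.
    """

    gridmask_keep_ratio: float = 0.6
    gridmask_unit_range: tuple[int, int] = (96, 224)
    row_blackout_period: int = 4
    noise_sigma: float = 0.05
    red_rotate_degrees: float = 45.0
    blur_sigma: float = 1.0
    target_size: tuple[int, int] = (224, 224)
    per_class_multiplicity: dict[str, int] = field(
        default_factory=lambda: dict(TABLE1_ADDED))

    def __post_init__(self):
        if not 0.0 < self.gridmask_keep_ratio <= 1.0:
            raise ValueError("gridmask_keep_ratio must be in (0, 1]")
        if self.row_blackout_period < 1:
            raise ValueError("row_blackout_period must be >= 1")
        if min(self.target_size) < 1:
            raise ValueError("target_size must be positive")
        if self.noise_sigma < 0 or self.blur_sigma < 0:
            raise ValueError("sigmas must be non-negative")


def _check_image(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3 or img.dtype != np.uint8:
        raise ValueError(f"expected (H, W, 3) uint8 RGB image, got "
                         f"shape {img.shape} dtype {img.dtype}")
    return img


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def gridmask(img: np.ndarray, keep_ratio: float = 0.6,
             unit_range: tuple[int, int] = (96, 224), seed=0) -> np.ndarray:
    """Periodic grid occlusion: within each d×d unit only a kept square of
    side ``ceil(keep_ratio * d)`` survives; the rest is set to black.

    The unit size d is drawn uniformly from ``unit_range`` and the grid
    phase uniformly from [0, d) per axis, so over many seeds the masked
    fraction approaches ``1 - keep_ratio**2``.
    """
    img = _check_image(img)
    h, w = img.shape[:2]
    lo, hi = int(unit_range[0]), int(unit_range[1])
    if lo > min(h, w):
        raise ValueError(f"grid unit {lo} larger than image {min(h, w)}")
    hi = min(hi, min(h, w))
    rng = _rng(seed)
    d = int(rng.integers(lo, hi + 1))
    keep = int(np.ceil(keep_ratio * d))
    py = int(rng.integers(0, d))
    px = int(rng.integers(0, d))
    yy = (np.arange(h) + py) % d < keep
    xx = (np.arange(w) + px) % d < keep
    mask = np.outer(yy, xx)
    out = img.copy()
    out[~mask] = 0
    return out


def row_blackout(img: np.ndarray, period: int = 4) -> np.ndarray:
    """Set every ``period``-th row (0-based indices ≡ period−1 mod period)
    to black."""
    img = _check_image(img)
    if period < 1:
        raise ValueError("period must be >= 1")
    out = img.copy()
    out[period - 1::period] = 0
    return out


def gaussian_noise(img: np.ndarray, sigma: float = 0.05, seed=0) -> np.ndarray:
    """Add i.i.d. zero-mean Gaussian noise of std ``sigma * 255`` per
    channel, then clip to [0, 255] and requantize."""
    img = _check_image(img)
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return img.copy()
    rng = _rng(seed)
    noisy = img.astype(np.float32) + rng.normal(0.0, sigma * 255.0, img.shape)
    return np.clip(np.rint(noisy), 0, 255).astype(np.uint8)


def red_channel_rotate(img: np.ndarray, degrees: float = 45.0) -> np.ndarray:
    """Rotate only the red channel about the image center (counterclockwise,
    bilinear resampling, out-of-frame filled with black); green and blue
    are untouched."""
    img = _check_image(img)
    if degrees % 360 == 0:
        return img.copy()
    red = img[:, :, 0].astype(np.float32)
    rot = ndimage.rotate(red, degrees, reshape=False, order=1,
                         mode="constant", cval=0.0)
    out = img.copy()
    out[:, :, 0] = np.clip(np.rint(rot), 0, 255).astype(np.uint8)
    return out


def gaussian_blur(img: np.ndarray, sigma: float = 1.0) -> np.ndarray:
    """Per-channel 2-D Gaussian blur with reflective borders; sigma 0 is
    the identity."""
    img = _check_image(img)
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return img.copy()
    blurred = np.empty_like(img, dtype=np.float32)
    for c in range(3):
        blurred[:, :, c] = ndimage.gaussian_filter(
            img[:, :, c].astype(np.float32), sigma, mode="reflect")
    return np.clip(np.rint(blurred), 0, 255).astype(np.uint8)


def resize_normalize(img: np.ndarray,
                     target_size: tuple[int, int] = (224, 224),
                     mean: tuple[float, float, float] = IMAGENET_MEAN,
                     std: tuple[float, float, float] = IMAGENET_STD) -> np.ndarray:
    """Bilinear resize to ``target_size``, scale to [0,1], channel-
    standardize, and return a float32 (3, H, W) array."""
    img = _check_image(img)
    h, w = target_size
    if img.shape[:2] != (h, w):
        img = np.asarray(Image.fromarray(img).resize((w, h), Image.BILINEAR))
    x = img.astype(np.float32) / 255.0
    x = (x - np.asarray(mean, np.float32)) / np.asarray(std, np.float32)
    return np.ascontiguousarray(x.transpose(2, 0, 1))


def dataset_statistics(images: np.ndarray) -> tuple[tuple[float, float, float],
                                                    tuple[float, float, float]]:
    """Per-channel mean and std of a uint8 image stack on the [0, 1] scale.

    Standardizing with the data's own statistics (rather than ImageNet's)
    is the appropriate choice when training from random initialization, and
    keeps a dark background near zero — the same value convolutional
    padding uses.
    """
    scaled = np.asarray(images, dtype=np.float64) / 255.0
    axes = tuple(range(scaled.ndim - 1))
    return (tuple(scaled.mean(axes)), tuple(scaled.std(axes)))


# ---------------------------------------------------------------------------
# operator chains and manifest expansion

_OPERATORS = ("gridmask", "rows", "noise", "redrot", "blur")


def _apply_chain(img: np.ndarray, chain: list[str], cfg: AugmentConfig,
                 rng: np.random.Generator) -> np.ndarray:
    for op in chain:
        if op == "gridmask":
            img = gridmask(img, cfg.gridmask_keep_ratio,
                           cfg.gridmask_unit_range, rng)
        elif op == "rows":
            img = row_blackout(img, cfg.row_blackout_period)
        elif op == "noise":
            img = gaussian_noise(img, cfg.noise_sigma, rng)
        elif op == "redrot":
            img = red_channel_rotate(img, cfg.red_rotate_degrees)
        elif op == "blur":
            img = gaussian_blur(img, cfg.blur_sigma)
        else:  # pragma: no cover - registry is closed
            raise ValueError(f"unknown operator '{op}'")
    return img


def _sample_chain(rng: np.random.Generator) -> list[str]:
    picked = [op for op in _OPERATORS if rng.random() < 0.5]
    if not picked:
        picked = [_OPERATORS[int(rng.integers(len(_OPERATORS)))]]
    return picked


def augment_training_set(manifest: DatasetManifest, cfg: AugmentConfig,
                         seed: int = 0,
                         images_root: str | Path | None = None,
                         out_root: str | Path | None = None) -> DatasetManifest:
    """Add augmented copies of training originals per the configured
    per-class counts.

    Sources cycle through a seeded shuffle of each class's training
    originals; each copy applies a seeded random operator chain whose names
    are embedded in the output filename.  The test split is never read or
    extended.  When ``images_root``/``out_root`` are given the augmented
    pixels are rendered and written; otherwise only the manifest grows.
    """
    rng = np.random.default_rng(seed)
    df = manifest.records
    unknown = set(cfg.per_class_multiplicity) - set(manifest.class_names)
    if unknown:
        raise ValueError(f"multiplicity given for unknown classes: {sorted(unknown)}")
    new_rows = []
    for cls in manifest.class_names:
        n_add = int(cfg.per_class_multiplicity.get(cls, 0))
        if n_add == 0:
            continue
        sources = df[(df["label"] == cls) & (df["split"] == "train")
                     & (df["provenance"] == "original")]["path"].to_numpy()
        if len(sources) == 0:
            raise ValueError(f"class '{cls}' has no training originals")
        order = rng.permutation(len(sources))
        for i in range(n_add):
            src = sources[order[i % len(sources)]]
            chain = _sample_chain(rng)
            stem = Path(src).stem
            new_path = f"{cls}/{stem}__aug{i:03d}__{'-'.join(chain)}.png"
            new_rows.append((new_path, cls, "train", "augmented", src))
            if images_root is not None and out_root is not None:
                img = np.asarray(Image.open(Path(images_root) / src).convert("RGB"))
                aug = _apply_chain(img, chain, cfg, rng)
                dest = Path(out_root) / new_path
                dest.parent.mkdir(parents=True, exist_ok=True)
                Image.fromarray(aug).save(dest)
    if not new_rows:
        return DatasetManifest(df.copy(), class_names=list(manifest.class_names))
    combined = pd.concat(
        [df, pd.DataFrame(new_rows, columns=COLUMNS)], ignore_index=True)
    return DatasetManifest(combined, class_names=list(manifest.class_names))
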