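"""Grad-CAM saliency maps, overlays, and localization scoring.

Grad-CAM weights each channel of a convolutional feature map by the
spatial mean of the gradient of the pre-softmax class score with respect
to that channel, sums the weighted activations, rectifies, min–max
normalizes to [0, 1] and bilinearly upsamples to the input resolution.
The softmax probability of the explained class is recorded from the same
forward pass.

The localization score measures what fraction of heatmap mass falls inside
a ground-truth bounding box (and whether the argmax pixel does) — on
synthetic data with planted glyphs this quantifies whether the classifier
attends to the discriminative region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image

from . import nn
from .architecture import softmax

__all__ = ["Heatmap", "gradcam", "overlay", "localization_score",
           "LocalizationResult"]


@dataclass
class Heatmap:
    values: np.ndarray            # (H, W) in [0, 1] at input resolution
    target_class: int
    softmax_score: float
    target_layer: str
    degenerate: bool = False      # raw map was identically <= 0


def _upsample_bilinear(m: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    h, w = size
    if m.shape == (h, w):
        return m
    return np.asarray(
        Image.fromarray(m.astype(np.float32), mode="F").resize(
            (w, h), Image.BILINEAR))


def gradcam(model, image: np.ndarray, class_index: int,
            target_layer: str | None = None) -> Heatmap:
    """Grad-CAM heatmap of ``class_index`` for one model-ready image
    (float32, (3, H, W)).

    ``target_layer`` must name a convolutional feature map recorded by the
    model's forward pass (``model.gradcam_layers()``); the default is the
    deepest backbone convolution.  The model is evaluated in inference mode
    but with gradients enabled.
    """
    image = np.asarray(image, dtype=np.float32)
    if image.ndim != 3:
        raise ValueError(f"expected one (3, H, W) image, got {image.shape}")
    target_layer = target_layer or model.default_gradcam_layer
    model.eval()
    logits = model.forward(nn.Tensor(image[None]))
    if target_layer not in model.activations:
        raise KeyError(
            f"unknown target layer '{target_layer}'; choose from "
            f"{model.gradcam_layers()}")
    act = model.activations[target_layer]
    k = logits.shape[1]
    if not 0 <= class_index < k:
        raise ValueError(f"class index {class_index} out of range [0, {k})")
    seed = np.zeros((1, k), dtype=np.float32)
    seed[0, class_index] = 1.0
    logits.backward(seed)
    grad = act.grad
    model.zero_grad()
    weights = grad.mean(axis=(2, 3), keepdims=True)           # (1, C, 1, 1)
    raw = np.maximum((weights * act.data).sum(axis=1)[0], 0.0)  # (h, w)
    degenerate = bool(raw.max() <= 0.0)
    if degenerate:
        values = np.zeros(image.shape[1:], dtype=np.float32)
    else:
        raw = (raw - raw.min()) / (raw.max() - raw.min())
        values = np.clip(_upsample_bilinear(raw, image.shape[1:]), 0.0, 1.0)
    score = float(softmax(logits.data[0])[class_index])
    return Heatmap(values, class_index, score, target_layer, degenerate)


def overlay(image: np.ndarray, heatmap: Heatmap, alpha: float = 0.5,
            cmap: str = "jet") -> np.ndarray:
    """Alpha-blend a color-mapped heatmap onto an 8-bit RGB image."""
    image = np.asarray(image)
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    if image.shape[:2] != heatmap.values.shape:
        raise ValueError(f"image {image.shape[:2]} and heatmap "
                         f"{heatmap.values.shape} shapes differ")
    import matplotlib
    colored = matplotlib.colormaps[cmap](heatmap.values)[:, :, :3] * 255.0
    blended = (1.0 - alpha) * image.astype(np.float64) + alpha * colored
    return np.clip(np.rint(blended), 0, 255).astype(np.uint8)


@dataclass
class LocalizationResult:
    mass_fraction: float          # heatmap mass inside the box / total mass
    argmax_inside: bool


def localization_score(heatmap: Heatmap,
                       box: tuple[int, int, int, int]) -> LocalizationResult:
    """Fraction of heatmap mass inside a half-open pixel box
    (x_min, y_min, x_max, y_max), plus whether the argmax pixel lies inside."""
    h, w = heatmap.values.shape
    x0, y0, x1, y1 = box
    if not (0 <= x0 < x1 <= w and 0 <= y0 < y1 <= h):
        raise ValueError(f"degenerate or out-of-bounds box {box} for "
                         f"heatmap {heatmap.values.shape}")
    total = float(heatmap.values.sum())
    inside = float(heatmap.values[y0:y1, x0:x1].sum())
    frac = inside / total if total > 0 else 0.0
    ay, ax = np.unravel_index(int(heatmap.values.argmax()),
                              heatmap.values.shape)
    return LocalizationResult(frac, bool(y0 <= ay < y1 and x0 <= ax < x1))
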