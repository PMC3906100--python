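"""Image rendering conventions for elemental and divergence maps.

Pure view layer: nothing here mutates the underlying data.  Elemental
images are displayed after a 2nd/98th-percentile intensity stretch;
multi-element figures are false-color RGB overlays of three stretched
images; divergence maps use a blue (similar) → yellow → red (divergent)
scale; weight maps render excluded pixels white and retained weights
gray→black over [λ, 1].  Data images are written as 32-bit float TIFF,
display renders as 8-bit PNG, each with a JSON manifest recording the
stretch and channel assignment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import tifffile
from PIL import Image

from .kl import DivergenceImage, WeightImage

__all__ = [
    "RenderSpec",
    "percentile_stretch",
    "rgb_overlay",
    "divergence_render",
    "weight_render",
    "write_tiff",
    "write_png",
    "write_manifest",
]


@dataclass(frozen=True)
class RenderSpec:
    """Stretch percentiles and overlay channel assignment."""

    low: float = 2.0
    high: float = 98.0
    overlay: dict | None = None   # e.g. {"Nd": "R", "Y": "G", "Fe": "B"}

    def __post_init__(self) -> None:
        if not (0 <= self.low < self.high <= 100):
            raise ValueError("require 0 <= low < high <= 100")


def percentile_stretch(image: np.ndarray, low: float = 2.0,
                       high: float = 98.0) -> np.ndarray:
    """Linear intensity stretch between the given percentiles, into [0, 1].

    Values at or below the low percentile map to 0, at or above the high
    percentile to 1.  NaNs are ignored for the percentile computation and
    map to 0; a constant image maps to all zeros.
    """
    img = np.asarray(image, float)
    finite = np.isfinite(img)
    if not finite.any():
        raise ValueError("image has no finite pixels")
    p_lo, p_hi = np.nanpercentile(np.where(finite, img, np.nan), [low, high])
    if p_hi <= p_lo:
        return np.zeros_like(img)
    out = (img - p_lo) / (p_hi - p_lo)
    out[~finite] = 0.0
    return np.clip(out, 0.0, 1.0)


def rgb_overlay(r_img: np.ndarray, g_img: np.ndarray,
                b_img: np.ndarray) -> np.ndarray:
    """Stack three stretched [0, 1] images into an 8-bit RGB image."""
    r, g, b = (np.asarray(x, float) for x in (r_img, g_img, b_img))
    if not (r.shape == g.shape == b.shape):
        raise ValueError("channel images must share one shape")
    rgb = np.stack([r, g, b], axis=-1)
    return (np.clip(rgb, 0, 1) * 255).round().astype(np.uint8)


# Anchor colors of the divergence scale: blue -> yellow -> red.
_DIV_ANCHORS = np.array([
    [0.05, 0.20, 0.95],
    [0.98, 0.92, 0.15],
    [0.90, 0.08, 0.05],
])
_INVALID_GRAY = 0.5


def _blue_yellow_red(values01: np.ndarray) -> np.ndarray:
    """Piecewise-linear interpolation through the anchor colors."""
    v = np.clip(values01, 0.0, 1.0)
    out = np.empty(v.shape + (3,))
    for ch in range(3):
        out[..., ch] = np.interp(v, [0.0, 0.5, 1.0], _DIV_ANCHORS[:, ch])
    return out


def divergence_render(div: DivergenceImage, low: float = 2.0,
                      high: float = 98.0) -> np.ndarray:
    """False-color 8-bit RGB of a divergence image.

    The stretch is applied to the finite values; invalid pixels (no
    counts) render neutral gray.  The reference pixel, at divergence 0,
    falls in the blue extreme.
    """
    values = np.where(div.valid, div.values, np.nan)
    stretched = percentile_stretch(values, low, high)
    rgb = _blue_yellow_red(stretched)
    rgb[~div.valid] = _INVALID_GRAY
    return (rgb * 255).round().astype(np.uint8)


def weight_render(weights: WeightImage) -> np.ndarray:
    """8-bit grayscale weight map: excluded white, λ→1 mapped gray→black."""
    lam = weights.threshold
    w = weights.weights
    gray = np.ones_like(w)                       # excluded pixels: white
    ret = weights.retained
    span = max(1.0 - lam, 1e-12)
    # retained: 0.75 (light gray) at w=λ down to 0 (black) at w=1
    gray[ret] = 0.75 * (1.0 - (w[ret] - lam) / span)
    return (np.clip(gray, 0, 1) * 255).round().astype(np.uint8)


def write_tiff(path, image: np.ndarray) -> None:
    """Write a data image as 32-bit float TIFF."""
    tifffile.imwrite(path, np.asarray(image, np.float32))


def write_png(path, image: np.ndarray) -> None:
    """Write an 8-bit display render (grayscale or RGB) as PNG."""
    arr = np.asarray(image)
    if arr.dtype != np.uint8:
        arr = (np.clip(arr, 0, 1) * 255).round().astype(np.uint8)
    Image.fromarray(arr).save(path)


def write_manifest(path, **entries) -> None:
    """Record render provenance (percentiles, channels, inputs) as JSON."""
    with open(path, "w") as f:
        json.dump(entries, f, indent=2, sort_keys=True, default=str)
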