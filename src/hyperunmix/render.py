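"""Visualization: thresholded RGB merges, component panels, composites.

Raw stacks are displayed as RGB merges of the three emission bands, each
channel scaled to its maximum after thresholding out the brightest 0.06% of
pixels (so a handful of hot pixels cannot crush the dynamic range).  Unmixed
coefficient maps are shown either as per-component grayscale panels annotated
with their maximum value on the epithelium=1 display scale, or combined into
a false-color composite with one color per tissue (epithelium yellow, lamina
propria white, collagen blue, lymphatic green).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .hyperstack import HyperStack, ValidationError
from .unmix import CoefficientMaps

#: Fraction of brightest pixels thresholded out per channel.
DEFAULT_CLIP_FRACTION = 0.0006

DEFAULT_COLORMAP = {
    "epithelium": (1.0, 1.0, 0.0),  # yellow
    "lamina_propria": (1.0, 1.0, 1.0),  # white
    "collagen": (0.0, 0.0, 1.0),  # blue
    "lymphatic": (0.0, 1.0, 0.0),  # green
}


@dataclass(frozen=True)
class RenderConfig:
    """Display conventions: hot-pixel clip fraction and component colors."""

    clip_fraction: float = DEFAULT_CLIP_FRACTION
    colormap: dict = field(default_factory=lambda: dict(DEFAULT_COLORMAP))

    def __post_init__(self) -> None:
        if not 0 <= self.clip_fraction < 0.01:
            raise ValidationError(
                f"clip_fraction must be in [0, 0.01), got {self.clip_fraction}"
            )
        for label, color in self.colormap.items():
            c = tuple(color)
            if len(c) != 3 or any(not 0 <= v <= 1 for v in c):
                raise ValidationError(f"color for {label!r} must be an RGB triple in [0,1]")


def quantize8(x: np.ndarray) -> np.ndarray:
    """Map [0, 1] floats to uint8 with half-up rounding."""
    return np.clip(np.floor(x * 255.0 + 0.5), 0, 255).astype(np.uint8)


def clip_value(channel: np.ndarray, clip_fraction: float) -> float:
    """Intensity at ascending-sorted index ``ceil((1 - f) * N)``.

    With f = 0.0006 on a 400x400 frame this saturates exactly 96 = f*N pixels
    of a strictly increasing image; ties at the clip value all saturate.
    f = 0 disables clipping (the plain maximum is used).
    """
    flat = np.asarray(channel, dtype=float).ravel()
    n = flat.size
    if n == 0:
        raise ValidationError("empty channel")
    idx = min(math.ceil((1.0 - clip_fraction) * n), n - 1)
    return float(np.partition(flat, idx)[idx])


def _scale_channel(channel: np.ndarray, clip_fraction: float) -> np.ndarray:
    cv = clip_value(channel, clip_fraction)
    if cv <= 0:
        return np.zeros_like(channel, dtype=float)
    return np.minimum(channel, cv) / cv


def rgb_merge(stack: HyperStack, ex_selection, cfg: RenderConfig | None = None) -> np.ndarray:
    """Average selected excitation frames and merge bands into 8-bit RGB.

    ``ex_selection`` is a single wavelength (nm) or an inclusive ``(low,
    high)`` range; frames are averaged unweighted.  Each channel is clipped
    at its thresholded maximum and scaled to full range independently, so the
    merge is invariant to a global positive intensity scale.
    """
    cfg = cfg or RenderConfig()
    if np.isscalar(ex_selection):
        indices = np.asarray([stack.excitation.index_of(float(ex_selection))])
    else:
        low, high = ex_selection
        indices = stack.excitation.select_range(low, high)
    if indices.size == 0:
        raise ValidationError(f"excitation selection {ex_selection} matches no frames")
    mean_frames = stack.data[:, :, indices, :].astype(float).mean(axis=2)
    out = np.zeros(stack.data.shape[:2] + (3,), dtype=np.uint8)
    # detector band -> display channel
    for band, channel in (("red", 0), ("green", 1), ("blue", 2)):
        b = stack.emission.index(band)
        out[:, :, channel] = quantize8(_scale_channel(mean_frames[:, :, b], cfg.clip_fraction))
    return out


def component_grayscale(maps: CoefficientMaps, label: str) -> tuple:
    """One component map as an 8-bit panel plus its max-value annotation.

    Requires display-scaled maps (reference component max = 1); the
    annotation is the component's maximum on that relative scale.  An
    all-zero map renders black with annotation 0.
    """
    if not maps.scaled:
        raise ValidationError("maps must be display-scaled before rendering panels")
    m = maps.component(label)
    peak = float(m.max())
    if peak <= 0:
        return np.zeros(m.shape, dtype=np.uint8), 0.0
    return quantize8(m / peak), peak


def false_color_composite(
    maps: CoefficientMaps, cfg: RenderConfig | None = None
) -> np.ndarray:
    """Merge all component maps into one 8-bit false-color RGB image.

    Each component map is normalized to its own maximum, tinted with its
    configured color, summed, and clipped to [0, 1] before quantization;
    all-zero components contribute nothing.
    """
    cfg = cfg or RenderConfig()
    if not maps.scaled:
        raise ValidationError("maps must be display-scaled before compositing")
    acc = np.zeros(maps.coeffs.shape[:2] + (3,), dtype=float)
    for label in maps.labels:
        if label not in cfg.colormap:
            raise ValidationError(f"no composite color configured for {label!r}")
        m = maps.component(label)
        peak = float(m.max())
        if peak <= 0:
            continue
        acc += (m / peak)[:, :, None] * np.asarray(cfg.colormap[label], dtype=float)
    return quantize8(np.clip(acc, 0.0, 1.0))


def save_png(image: np.ndarray, path) -> Path:
    from PIL import Image

    path = Path(path)
    Image.fromarray(image).save(path)
    return path
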