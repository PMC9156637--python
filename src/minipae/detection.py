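"""Residual detection maps: localising candidate emphysema regions.

The residual |X - X'| between an input slice and its reconstruction is
high wherever the generator — trained only on normal lungs — failed to
reproduce the input. Thresholding the residual, keeping only pixels inside
the lungs and dropping tiny speckle components yields a binary candidate
mask; overlaying it on the input gives the visual quality-check image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

#: minimum candidate-component area in pixels at 64-px scale; scaled by
#: (image_size / 64)**2 for larger models
MIN_AREA_AT_64 = 5


@dataclass
class DetectionMap:
    residual: np.ndarray
    candidate_mask: np.ndarray
    slice_index: int = 0
    threshold: float = 0.0


def residual_map(x: np.ndarray, xp: np.ndarray) -> np.ndarray:
    """Elementwise absolute difference |X - X'|.

    For slices normalised into [-1, 1] the residual is bounded by 2.
    """
    x, xp = np.asarray(x), np.asarray(xp)
    if x.shape != xp.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {xp.shape}")
    return np.abs(x - xp)


def residual_threshold(normal_residuals, q: float = 95.0) -> float:
    """Default binarisation threshold: the q-th percentile of residual
    values pooled over held-out normal slices."""
    pooled = np.concatenate([np.asarray(r).ravel() for r in normal_residuals])
    return float(np.percentile(pooled, q))


def candidate_regions(
    residual: np.ndarray,
    lung_mask_slice: np.ndarray,
    threshold: float,
    min_area: int | None = None,
    slice_index: int = 0,
) -> DetectionMap:
    """Binarise a residual into lung-restricted candidate regions.

    candidate = (residual > threshold) AND lung mask, with connected
    components smaller than ``min_area`` pixels removed. A higher threshold
    always yields a subset mask.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    if min_area is None:
        min_area = max(1, round(MIN_AREA_AT_64 * (residual.shape[-1] / 64) ** 2))
    mask = (residual > threshold) & np.asarray(lung_mask_slice, dtype=bool)
    labels, n = ndimage.label(mask)
    if n:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        small = np.flatnonzero(sizes < min_area) + 1
        if small.size:
            mask &= ~np.isin(labels, small)
    return DetectionMap(residual=residual, candidate_mask=mask, slice_index=slice_index, threshold=threshold)


def overlay(detection: DetectionMap, x: np.ndarray, tint=(0.0, 0.8, 0.0), alpha: float = 0.5) -> np.ndarray:
    """Render a slice with candidate regions tinted (default green).

    Pure rendering: returns an (H, W, 3) uint8 RGB array and never touches
    the detection map itself.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.shape != detection.candidate_mask.shape:
        raise ValueError("slice and candidate mask shapes differ")
    lo, hi = x.min(), x.max()
    gray = (x - lo) / (hi - lo) if hi > lo else np.zeros_like(x)
    rgb = np.repeat(gray[..., None], 3, axis=-1)
    m = detection.candidate_mask
    for c, t in enumerate(tint):
        rgb[..., c][m] = (1 - alpha) * rgb[..., c][m] + alpha * t
    return (np.clip(rgb, 0, 1) * 255).astype(np.uint8)


def save_overlay(detection: DetectionMap, x: np.ndarray, path) -> None:
    """Write the overlay rendering as a PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plt.imsave(str(path), overlay(detection, x))
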