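"""Lung segmentation and quantitative emphysema measurement (%LAA).

%LAA-950 — the percentage of lung voxels with attenuation strictly below
-950 HU — is the standard densitometric emphysema measure; scans with
%LAA > 5% are categorised as emphysema. Lung segmentation is fully
automatic: threshold at -320 HU, discard air connected to the volume
border, keep the two largest remaining components (left and right lung),
and close small holes left by vessels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.segmentation import clear_border

from .volume_io import CTVolume

LAA_THRESHOLD_HU = -950.0
LAA_CUTOFF_PCT = 5.0
LUNG_THRESHOLD_HU = -320.0

CAT_NON_EMPHYSEMA = "non-emphysema"
CAT_EMPHYSEMA = "emphysema"


class SegmentationError(RuntimeError):
    """Raised when no lung-like component can be found."""


@dataclass
class LungMask:
    mask: np.ndarray

    @property
    def voxel_count(self) -> int:
        return int(np.count_nonzero(self.mask))


@dataclass
class DensitometryResult:
    laa_pct: float
    threshold_hu: float = LAA_THRESHOLD_HU
    cutoff_pct: float = LAA_CUTOFF_PCT

    @property
    def category(self) -> str:
        return categorize(self, self.cutoff_pct)


def segment_lungs(vol: CTVolume, threshold_hu: float = LUNG_THRESHOLD_HU) -> LungMask:
    """Threshold-and-morphology lung segmentation.

    Keeps the two largest internal air components; raises
    :class:`SegmentationError` when the volume contains no internal air
    (e.g. a solid soft-tissue phantom).
    """
    air = vol.voxels < threshold_hu
    internal = clear_border(air)  # drop air connected to any volume border
    labels, n = ndimage.label(internal)
    if n < 1:
        raise SegmentationError("no internal air component found; cannot segment lungs")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = np.argsort(sizes)[::-1][:2] + 1
    mask = np.isin(labels, keep)
    mask = ndimage.binary_closing(mask, structure=np.ones((3, 3, 3), dtype=bool))
    mask = ndimage.binary_fill_holes(mask)
    return LungMask(mask=mask)


def percent_laa(
    vol: CTVolume,
    mask: LungMask | np.ndarray,
    threshold_hu: float = LAA_THRESHOLD_HU,
    cutoff_pct: float = LAA_CUTOFF_PCT,
) -> DensitometryResult:
    """%LAA: share of lung voxels with HU strictly below ``threshold_hu``."""
    m = mask.mask if isinstance(mask, LungMask) else np.asarray(mask, dtype=bool)
    if m.shape != vol.voxels.shape:
        raise ValueError("mask shape does not match volume")
    n = np.count_nonzero(m)
    if n == 0:
        raise ValueError("empty lung mask")
    laa = 100.0 * np.count_nonzero(vol.voxels[m] < threshold_hu) / n
    return DensitometryResult(laa_pct=laa, threshold_hu=threshold_hu, cutoff_pct=cutoff_pct)


def categorize(result: DensitometryResult | float, cutoff_pct: float = LAA_CUTOFF_PCT) -> str:
    """%LAA <= cutoff is non-emphysema; strictly above is emphysema."""
    laa = result.laa_pct if isinstance(result, DensitometryResult) else float(result)
    return CAT_EMPHYSEMA if laa > cutoff_pct else CAT_NON_EMPHYSEMA
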