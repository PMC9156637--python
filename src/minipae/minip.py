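"""Sliding-slab minimum intensity projection (minIP) along the axial axis.

A minIP slab replaces each axial slice by the voxelwise minimum over a
centred window of neighbouring slices. Low-attenuation structures (emphysema)
survive the minimum while bright, thin structures (vessels) whose in-plane
position shifts with depth are suppressed — which is why minIP acts as a
disease-specific augmentation for emphysema.

Slabs here are centred and stride-1: one output slice per input slice, so
slice indexing stays aligned with per-slice labels. Edge windows are clamped
to the volume (no padding value is physically neutral for a minimum).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import minimum_filter1d

from .volume_io import CTVolume

#: the slab thicknesses evaluated by default: 1 to 11 mm in 2-mm steps
DEFAULT_THICKNESSES_MM = (1, 3, 5, 7, 9, 11)


@dataclass
class MinIPStack:
    """Per-slice minimum projections of a volume at one slab thickness."""

    slabs: np.ndarray
    slab_thickness_mm: float
    slab_thickness_slices: int
    source: str = ""
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    @property
    def n_slices(self) -> int:
        return self.slabs.shape[0]


def mm_to_slices(thickness_mm: float, increment_mm: float) -> int:
    """Number of slices in a slab: the largest odd k with k*increment <= thickness.

    Clamped below so a slab is never thinner than one slice (k >= 1), and
    rounded down to odd so the window stays centred on its output slice.
    """
    if thickness_mm <= 0 or increment_mm <= 0:
        raise ValueError("thickness and increment must be positive")
    k = int(np.floor(max(thickness_mm, increment_mm) / increment_mm + 1e-9))
    if k % 2 == 0:
        k -= 1
    return max(k, 1)


def project_minip(vol: CTVolume, thickness_mm: float) -> MinIPStack:
    """Project a volume into minIP slabs of the given thickness.

    Output slice i is the voxelwise minimum over input slices
    [i-(k-1)/2, i+(k-1)/2] clamped to the volume bounds; k comes from
    :func:`mm_to_slices`. A 1-slice slab returns the volume unchanged.
    """
    if vol.n_slices < 1:
        raise ValueError("volume has no slices")
    k = mm_to_slices(thickness_mm, vol.slice_increment_mm)
    if k == 1:
        slabs = vol.voxels.copy()
    else:
        # edge-clamped centred window == minimum filter with edge replication
        slabs = minimum_filter1d(vol.voxels, size=k, axis=0, mode="nearest")
    return MinIPStack(
        slabs=slabs,
        slab_thickness_mm=float(thickness_mm),
        slab_thickness_slices=k,
        source=vol.participant_id,
        spacing_mm=vol.spacing_mm,
    )


def slab_settings(thicknesses_mm=None) -> list[float]:
    """Validate and return the list of slab thicknesses to evaluate."""
    if thicknesses_mm is None:
        return list(DEFAULT_THICKNESSES_MM)
    out = [float(t) for t in thicknesses_mm]
    if not out:
        raise ValueError("at least one slab thickness is required")
    if any(t <= 0 for t in out):
        raise ValueError("slab thicknesses must be positive")
    return out
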