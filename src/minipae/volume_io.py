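"""Reading, writing and resampling of chest-CT volumes.

A :class:`CTVolume` holds Hounsfield-unit voxels on an axial-first grid
(axis 0 = superior->inferior slices). Volumes are persisted as NIfTI via
nibabel; DICOM series directories are imported with pydicom, applying the
rescale slope/intercept to recover HU. Axial resampling is linear
interpolation along axis 0 only — in-plane geometry is never touched —
which is how scans with differing slice increments are brought onto a
common grid before slab projection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom

HU_MIN = -1024
HU_MAX = 3071

#: HU window used to normalise slices for model input: a lung window over
#: the aerated-parenchyma range. Bright structure (vessels, chest wall)
#: clips flat at +1, spending the dynamic range on the low-attenuation
#: signal the anomaly detector must see.
MODEL_WINDOW_HU = (-1000.0, -600.0)

#: wide window covering parenchyma through vessels; used for rendering.
FULL_WINDOW_HU = (-1000.0, 400.0)


@dataclass
class CTVolume:
    """A 3-D CT volume in Hounsfield units.

    Attributes
    ----------
    voxels : ndarray, shape (slices, rows, cols)
        HU values; axis 0 is the axial (superior->inferior) axis.
    spacing_mm : tuple of float
        (slice_increment, row_spacing, col_spacing) in mm.
    slice_thickness_mm : float
        Acquired slice thickness (may exceed the increment when slices
        overlap).
    participant_id : str
    """

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]
    slice_thickness_mm: float = 1.0
    participant_id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3-D voxel array, got ndim={self.voxels.ndim}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxels must be finite")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be positive, got {self.spacing_mm}")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def slice_increment_mm(self) -> float:
        return float(self.spacing_mm[0])

    @property
    def axial_extent_mm(self) -> float:
        """Distance between the first and last slice centres."""
        return (self.n_slices - 1) * self.slice_increment_mm


@dataclass
class NormalizedSlice:
    """A single axial slice windowed and affinely mapped into [-1, 1]."""

    pixels: np.ndarray
    window_hu: tuple[float, float]
    source_index: int = 0


def write_volume(vol: CTVolume, path: str | Path) -> Path:
    """Write a volume as NIfTI (.nii or .nii.gz), quantising HU to int16.

    Stores voxels axial-first in data order; the affine encodes voxel
    spacing. A JSON sidecar records the slice thickness and participant id.
    """
    path = Path(path)
    data = np.rint(np.clip(vol.voxels, HU_MIN, HU_MAX)).astype(np.int16)
    # nibabel convention is (x, y, z); keep axial as the last file axis
    affine = np.diag([vol.spacing_mm[2], vol.spacing_mm[1], vol.spacing_mm[0], 1.0])
    img = nib.Nifti1Image(np.transpose(data, (2, 1, 0)), affine)
    img.header.set_zooms((vol.spacing_mm[2], vol.spacing_mm[1], vol.spacing_mm[0]))
    nib.save(img, str(path))
    sidecar = path.with_suffix("").with_suffix("")  # strip .nii(.gz)
    meta = {
        "participant_id": vol.participant_id,
        "slice_thickness_mm": vol.slice_thickness_mm,
    }
    Path(str(sidecar) + ".json").write_text(json.dumps(meta))
    return path


def _read_nifti(path: Path) -> CTVolume:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise IOError(f"{path}: expected a 3-D NIfTI, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    voxels = np.transpose(data, (2, 1, 0)).astype(np.float64)
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    meta_path = Path(str(path.with_suffix("").with_suffix("")) + ".json")
    pid, thickness = "", spacing[0]
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        pid = meta.get("participant_id", "")
        thickness = float(meta.get("slice_thickness_mm", spacing[0]))
    return CTVolume(voxels, spacing, slice_thickness_mm=thickness, participant_id=pid)


def _read_dicom_series(path: Path) -> CTVolume:
    files = sorted(p for p in path.iterdir() if p.suffix.lower() in {".dcm", ""} and p.is_file())
    datasets = []
    for f in files:
        try:
            datasets.append(pydicom.dcmread(str(f)))
        except Exception:
            continue
    if not datasets:
        raise IOError(f"{path}: no readable DICOM files")
    # order by z of ImagePositionPatient (fallback: InstanceNumber)
    try:
        datasets.sort(key=lambda d: float(d.ImagePositionPatient[2]))
        zs = [float(d.ImagePositionPatient[2]) for d in datasets]
    except AttributeError:
        datasets.sort(key=lambda d: int(d.InstanceNumber))
        zs = list(range(len(datasets)))
    dz = np.diff(zs)
    if len(dz) and (np.any(dz <= 0) or not np.allclose(dz, dz[0], atol=1e-3)):
        raise IOError(f"{path}: non-monotonic or irregular slice positions")
    slices = []
    for d in datasets:
        slope = float(getattr(d, "RescaleSlope", 1.0))
        intercept = float(getattr(d, "RescaleIntercept", 0.0))
        slices.append(d.pixel_array.astype(np.float64) * slope + intercept)
    d0 = datasets[0]
    row_sp, col_sp = (float(x) for x in d0.PixelSpacing)
    increment = float(dz[0]) if len(dz) else float(getattr(d0, "SliceThickness", 1.0))
    return CTVolume(
        np.stack(slices, axis=0),
        (increment, row_sp, col_sp),
        slice_thickness_mm=float(getattr(d0, "SliceThickness", increment)),
        participant_id=str(getattr(d0, "PatientID", "")),
    )


def read_volume(path: str | Path) -> CTVolume:
    """Read a CT volume from a NIfTI file or a DICOM series directory."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file or directory: {path}")
    if path.is_dir():
        return _read_dicom_series(path)
    return _read_nifti(path)


def resample_axial(vol: CTVolume, target_increment_mm: float) -> CTVolume:
    """Resample the volume to a new slice increment along the axial axis.

    Linear interpolation along axis 0 only; the in-plane grid is unchanged.
    The new grid spans the same axial extent (first to last slice centre),
    with ``round(extent / target) + 1`` slices. Interpolation is convex, so
    the global min and max of the volume cannot be exceeded.
    """
    if target_increment_mm <= 0:
        raise ValueError("target increment must be positive")
    if vol.n_slices < 2:
        raise ValueError("need at least 2 slices to resample")
    if np.isclose(target_increment_mm, vol.slice_increment_mm):
        return vol
    extent = vol.axial_extent_mm
    n_new = int(round(extent / target_increment_mm)) + 1
    old_z = np.arange(vol.n_slices) * vol.slice_increment_mm
    new_z = np.clip(np.arange(n_new) * target_increment_mm, 0, extent)
    # vectorised 1-D linear interpolation down the stack
    idx = np.searchsorted(old_z, new_z, side="right") - 1
    idx = np.clip(idx, 0, vol.n_slices - 2)
    frac = (new_z - old_z[idx]) / vol.slice_increment_mm
    frac = frac[:, None, None]
    new_vox = (1 - frac) * vol.voxels[idx] + frac * vol.voxels[idx + 1]
    return replace(vol, voxels=new_vox, spacing_mm=(float(target_increment_mm),) + vol.spacing_mm[1:])


def normalize_hu(
    slice_hu: np.ndarray,
    window_hu: tuple[float, float] = MODEL_WINDOW_HU,
    source_index: int = 0,
) -> NormalizedSlice:
    """Affinely map the HU window [low, high] onto [-1, 1], clipping outside.

    With a (-1000, 400) HU window, -950 HU maps to -0.9286.
    """
    low, high = window_hu
    if not low < high:
        raise ValueError(f"window low must be < high, got {window_hu}")
    x = np.asarray(slice_hu, dtype=np.float64)
    pixels = np.clip(2.0 * (x - low) / (high - low) - 1.0, -1.0, 1.0)
    return NormalizedSlice(pixels=pixels, window_hu=(float(low), float(high)), source_index=source_index)
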