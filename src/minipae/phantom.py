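"""Synthetic chest-CT phantoms with known emphysema ground truth.

Every downstream stage (slab projection, densitometry, the anomaly model,
screening, evaluation) is exercised on these phantoms, so the geometry is
deliberately simple but covers the features the method depends on:

* an elliptic-cylinder soft-tissue body (~+40 HU) surrounded by air,
* two ellipsoidal lungs filled with noisy parenchyma (default -850 +- 40 HU,
  the attenuation of normally aerated lung),
* bright tilted cylindrical vessels inside the lungs (+50 HU) whose in-plane
  position drifts with depth, so minimum-intensity slabs progressively
  suppress them,
* optional spherical low-attenuation lesions (default -980 +- 10 HU, safely
  below the -950 HU emphysema threshold) with an exact voxel mask.

HU are quantised to integers before the volume leaves this module, so file
round-trips are exact and results reproduce across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .volume_io import HU_MAX, HU_MIN, CTVolume

LABEL_NORMAL = "normal"
LABEL_EMPHYSEMA = "emphysema"

#: HU spread of lesion voxels around ``lesion_hu_mean`` (before scan noise).
LESION_HU_SD = 10.0


class LesionPlacementError(RuntimeError):
    """Raised when a lesion cannot be placed fully inside a lung."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic chest-CT volume.

    Defaults give a 48 x 64 x 64 grid at (1, 4, 4) mm spacing: 1-mm slice
    increment (so 1-11 mm slabs are meaningful) and an in-plane matrix that
    feeds the 64-pixel test-scale model directly.
    """

    shape: tuple[int, int, int] = (48, 64, 64)
    spacing_mm: tuple[float, float, float] = (1.0, 4.0, 4.0)
    parenchyma_hu_mean: float = -850.0
    parenchyma_hu_sd: float = 40.0
    vessel_count: int = 6
    vessel_hu: float = 50.0
    lesion_count: int = 0
    lesion_radius_mm: float = 12.0
    lesion_hu_mean: float = -980.0
    noise_sd: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.vessel_count < 0 or self.lesion_count < 0:
            raise ValueError("counts must be non-negative")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be positive")
        if self.lesion_count > 0 and not self.lesion_hu_mean < self.parenchyma_hu_mean:
            raise ValueError("lesions must be darker than parenchyma")


@dataclass
class PhantomTruth:
    """Ground truth accompanying a phantom volume."""

    lung_mask: np.ndarray
    lesion_mask: np.ndarray
    label: str
    expected_laa_pct: float
    vessel_mask: np.ndarray | None = None


def _mm_grid(shape, spacing):
    """Voxel-centre coordinates in mm, one array per axis."""
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid(zz, yy, xx, center, semi):
    return (
        ((zz - center[0]) / semi[0]) ** 2
        + ((yy - center[1]) / semi[1]) ** 2
        + ((xx - center[2]) / semi[2]) ** 2
    ) <= 1.0


def generate_phantom(spec: PhantomSpec) -> tuple[CTVolume, PhantomTruth]:
    """Build one phantom volume plus its ground truth.

    The same spec (including its seed) always yields bit-identical integer
    HU. Raises :class:`LesionPlacementError` if a lesion cannot fit inside
    a lung.
    """
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.shape
    zz, yy, xx = _mm_grid(spec.shape, spec.spacing_mm)
    cz, cy, cx = ((n - 1) * s / 2 for n, s in zip(spec.shape, spec.spacing_mm))
    ey, ex = (ny - 1) * spec.spacing_mm[1], (nx - 1) * spec.spacing_mm[2]

    # elliptic-cylinder body spanning the full axial range
    body = (((yy - cy) / (0.42 * ey)) ** 2 + ((xx - cx) / (0.46 * ex)) ** 2) <= 1.0

    # two ellipsoidal lungs, well inside the body and off the z borders
    lung_semi = (0.42 * (nz - 1) * spec.spacing_mm[0], 0.22 * ey, 0.15 * ex)
    lung_l = _ellipsoid(zz, yy, xx, (cz, cy, cx - 0.21 * ex), lung_semi)
    lung_r = _ellipsoid(zz, yy, xx, (cz, cy, cx + 0.21 * ex), lung_semi)
    lungs = lung_l | lung_r

    hu = np.full(spec.shape, -1000.0)
    hu[body] = 40.0
    hu[lungs] = spec.parenchyma_hu_mean + spec.parenchyma_hu_sd * rng.standard_normal(
        np.count_nonzero(lungs)
    )

    # tilted vessels: bright cylinders whose (y, x) position drifts with z,
    # so a minimum over neighbouring slices replaces them with parenchyma
    vessel_mask = np.zeros(spec.shape, dtype=bool)
    pts = np.stack([zz, yy, xx], axis=-1)
    lung_idx = np.argwhere(lungs)
    for _ in range(spec.vessel_count):
        if lung_idx.size == 0:
            break
        p0 = lung_idx[rng.integers(len(lung_idx))] * np.asarray(spec.spacing_mm)
        tilt = rng.uniform(1.0, 3.0, size=2) * rng.choice([-1.0, 1.0], size=2)
        d = np.array([1.0, tilt[0], tilt[1]])
        d /= np.linalg.norm(d)
        rel = pts - p0
        dist = np.linalg.norm(rel - (rel @ d)[..., None] * d, axis=-1)
        vessel_mask |= (dist < 5.0) & lungs
    hu[vessel_mask] = spec.vessel_hu

    # spherical lesions placed fully inside a lung
    lesion_mask = np.zeros(spec.shape, dtype=bool)
    r = spec.lesion_radius_mm
    for _ in range(spec.lesion_count):
        placed = False
        for _attempt in range(200):
            c = lung_idx[rng.integers(len(lung_idx))] * np.asarray(spec.spacing_mm)
            sphere = (
                ((zz - c[0]) / r) ** 2 + ((yy - c[1]) / r) ** 2 + ((xx - c[2]) / r) ** 2
            ) <= 1.0
            if sphere.any() and not (sphere & ~lungs).any():
                lesion_mask |= sphere
                placed = True
                break
        if not placed:
            raise LesionPlacementError(
                f"could not place a {r:g}-mm lesion inside the lungs after 200 attempts"
            )
    n_les = np.count_nonzero(lesion_mask)
    if n_les:
        hu[lesion_mask] = spec.lesion_hu_mean + LESION_HU_SD * rng.standard_normal(n_les)

    hu += spec.noise_sd * rng.standard_normal(spec.shape)
    hu = np.rint(np.clip(hu, HU_MIN, HU_MAX)).astype(np.int16)

    lung_n = np.count_nonzero(lungs)
    laa_pct = 100.0 * np.count_nonzero((hu < -950) & lungs) / lung_n if lung_n else 0.0
    vol = CTVolume(
        hu.astype(np.float64),
        spec.spacing_mm,
        slice_thickness_mm=spec.spacing_mm[0],
        participant_id=f"phantom-{spec.seed}",
    )
    truth = PhantomTruth(
        lung_mask=lungs,
        lesion_mask=lesion_mask,
        label=LABEL_EMPHYSEMA if spec.lesion_count > 0 else LABEL_NORMAL,
        expected_laa_pct=laa_pct,
        vessel_mask=vessel_mask,
    )
    return vol, truth


#: lesions given to emphysema participants when the template has none
DEFAULT_EMPHYSEMA_LESIONS = 3


def generate_cohort(
    n_normal: int,
    n_emphysema: int,
    spec_template: PhantomSpec = PhantomSpec(),
    seed: int = 0,
) -> list[tuple[CTVolume, PhantomTruth]]:
    """Generate a cohort of phantoms with per-participant derived seeds.

    The first ``n_normal`` participants have no lesions; the remaining
    ``n_emphysema`` carry ``spec_template.lesion_count`` lesions (or
    :data:`DEFAULT_EMPHYSEMA_LESIONS` if the template specifies none).
    """
    if n_normal < 0 or n_emphysema < 0:
        raise ValueError("cohort sizes must be non-negative")
    ss = np.random.SeedSequence(seed)
    n_total = n_normal + n_emphysema
    child_seeds = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n_total)]
    out = []
    for i in range(n_total):
        if i < n_normal:
            spec = replace(spec_template, lesion_count=0, seed=child_seeds[i])
        else:
            n_les = spec_template.lesion_count or DEFAULT_EMPHYSEMA_LESIONS
            spec = replace(spec_template, lesion_count=n_les, seed=child_seeds[i])
        vol, truth = generate_phantom(spec)
        vol.participant_id = f"P{i:04d}"
        out.append((vol, truth))
    return out


def write_cohort(cohort, outdir) -> "pandas.DataFrame":
    """Persist a cohort: NIfTI per participant, JSON truth sidecar, CSV manifest."""
    import json
    from pathlib import Path

    import pandas as pd

    from .volume_io import write_volume

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for vol, truth in cohort:
        path = outdir / f"{vol.participant_id}.nii.gz"
        write_volume(vol, path)
        sidecar = outdir / f"{vol.participant_id}.truth.json"
        sidecar.write_text(
            json.dumps(
                {
                    "label": truth.label,
                    "expected_laa_pct": truth.expected_laa_pct,
                    "lesion_voxels": int(np.count_nonzero(truth.lesion_mask)),
                }
            )
        )
        rows.append({"participant_id": vol.participant_id, "label": truth.label, "path": str(path)})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return manifest
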