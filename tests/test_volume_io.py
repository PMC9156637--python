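"""Volume I/O: NIfTI round-trips, DICOM HU rescaling, resampling, windowing."""

import numpy as np
import pydicom
import pytest
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from minipae.volume_io import (
    CTVolume,
    normalize_hu,
    read_volume,
    resample_axial,
    write_volume,
)


def test_nifti_round_trip_preserves_integer_hu_and_spacing(tmp_path, emphysema_phantom):
    vol, _ = emphysema_phantom
    path = tmp_path / "p.nii.gz"
    write_volume(vol, path)
    back = read_volume(path)
    assert np.array_equal(back.voxels, vol.voxels)
    assert back.spacing_mm == pytest.approx(vol.spacing_mm, rel=1e-6)
    assert back.participant_id == vol.participant_id


def test_read_missing_file_raises():
    with pytest.raises(IOError):
        read_volume("/nonexistent/volume.nii.gz")


def _make_dicom_slice(path, z, rows=4, cols=4, slope=2.0, intercept=-1024.0, stored=None):
    ds = Dataset()
    ds.file_meta = FileMetaDataset()
    ds.file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds.file_meta.MediaStorageSOPClassUID = generate_uid()
    ds.file_meta.MediaStorageSOPInstanceUID = generate_uid()
    ds.SOPClassUID = ds.file_meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = ds.file_meta.MediaStorageSOPInstanceUID
    ds.PatientID = "T1"
    ds.Rows, ds.Columns = rows, cols
    ds.PixelSpacing = [0.7, 0.7]
    ds.SliceThickness = 3.0
    ds.ImagePositionPatient = [0.0, 0.0, z]
    ds.InstanceNumber = int(z)
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 1
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.RescaleSlope = slope
    ds.RescaleIntercept = intercept
    arr = stored if stored is not None else np.zeros((rows, cols), dtype=np.int16)
    ds.PixelData = arr.astype(np.int16).tobytes()
    ds.save_as(str(path), enforce_file_format=True)


def test_dicom_series_applies_rescale_slope_intercept(tmp_path):
    """HU = slope * stored + intercept on a hand-built 2-slice series."""
    d = tmp_path / "series"
    d.mkdir()
    stored0 = np.arange(16, dtype=np.int16).reshape(4, 4)
    stored1 = np.full((4, 4), 100, dtype=np.int16)
    _make_dicom_slice(d / "a.dcm", z=0.0, stored=stored0)
    _make_dicom_slice(d / "b.dcm", z=3.0, stored=stored1)
    vol = read_volume(d)
    assert vol.voxels.shape == (2, 4, 4)
    np.testing.assert_allclose(vol.voxels[0], 2.0 * stored0 - 1024.0)
    np.testing.assert_allclose(vol.voxels[1], 2.0 * 100 - 1024.0)
    # anisotropic spacing preserved: 3.0 mm increment, 0.7 mm in-plane
    assert vol.spacing_mm == pytest.approx((3.0, 0.7, 0.7))


def test_dicom_duplicate_slice_positions_rejected(tmp_path):
    d = tmp_path / "series"
    d.mkdir()
    _make_dicom_slice(d / "a.dcm", z=0.0)
    _make_dicom_slice(d / "b.dcm", z=0.0)
    with pytest.raises(IOError):
        read_volume(d)


class TestResampleAxial:
    def test_identity_when_target_equals_increment(self):
        vol = CTVolume(np.zeros((5, 3, 3)), (1.0, 1.0, 1.0))
        out = resample_axial(vol, 1.0)
        assert np.array_equal(out.voxels, vol.voxels)

    def test_linear_midpoint(self):
        vox = np.stack([np.zeros((2, 2)), np.full((2, 2), 100.0)])
        vol = CTVolume(vox, (1.0, 1.0, 1.0))
        out = resample_axial(vol, 0.5)
        assert out.voxels.shape[0] == 3
        np.testing.assert_allclose(out.voxels[1], 50.0)

    def test_bounds_preserved_by_convex_interpolation(self, emphysema_phantom):
        vol, _ = emphysema_phantom
        out = resample_axial(vol, 0.7)
        assert out.voxels.min() >= vol.voxels.min() - 1e-9
        assert out.voxels.max() <= vol.voxels.max() + 1e-9

    def test_laa_stable_under_resampling(self, emphysema_phantom):
        """%LAA changes by < 1 percentage point after axial resampling."""
        from minipae.densitometry import percent_laa, segment_lungs

        vol, _ = emphysema_phantom
        res = resample_axial(vol, 0.7)
        laa0 = percent_laa(vol, segment_lungs(vol)).laa_pct
        laa1 = percent_laa(res, segment_lungs(res)).laa_pct
        assert abs(laa0 - laa1) < 1.0

    def test_single_slice_rejected(self):
        vol = CTVolume(np.zeros((1, 2, 2)), (1.0, 1.0, 1.0))
        with pytest.raises(ValueError):
            resample_axial(vol, 0.5)


class TestNormalizeHu:
    def test_window_endpoints_map_to_plus_minus_one(self):
        s = normalize_hu(np.array([[-1000.0, 400.0]]), (-1000, 400))
        np.testing.assert_allclose(s.pixels, [[-1.0, 1.0]])

    def test_window_midpoint_maps_to_zero(self):
        s = normalize_hu(np.array([[-300.0]]), (-1000, 400))
        assert s.pixels[0, 0] == pytest.approx(0.0)

    def test_closed_form_affine_value(self):
        """-950 HU in a (-1000, 400) window maps to -0.9286."""
        s = normalize_hu(np.array([[-950.0]]), (-1000, 400))
        assert s.pixels[0, 0] == pytest.approx(2 * 50 / 1400 - 1, abs=1e-9)
        assert s.pixels[0, 0] == pytest.approx(-0.9286, abs=5e-5)

    def test_values_clipped_outside_window(self):
        s = normalize_hu(np.array([[-2000.0, 3000.0]]), (-1000, 400))
        np.testing.assert_allclose(s.pixels, [[-1.0, 1.0]])

    def test_degenerate_window_rejected(self):
        with pytest.raises(ValueError):
            normalize_hu(np.zeros((2, 2)), (400, -1000))
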