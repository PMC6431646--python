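"""Volume containers, I/O round-trips, resampling and label utilities."""

import numpy as np
import pydicom
import pytest
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from scipy import ndimage

import ctbrainseg as cb
from ctbrainseg.volumes import VolumeError, VolumeIOError


def _vol(data, spacing=(1, 1, 1), modality="ct"):
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    return cb.ImageVolume(np.asarray(data, float), spacing, aff, modality)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

def test_volume_invariants_enforced():
    with pytest.raises(VolumeError):
        _vol(np.zeros((4, 4, 4)), spacing=(1, 0, 1))
    with pytest.raises(VolumeError):
        cb.ImageVolume(np.zeros((4, 4, 4)), (1, 1, 1), np.zeros((4, 4)))
    with pytest.raises(VolumeError):
        _vol(np.full((4, 4, 4), 2.0), modality="probability")
    with pytest.raises(VolumeError):
        cb.LabelMap(np.full((3, 3, 3), 7))


# ---------------------------------------------------------------------------
# NIfTI and DICOM I/O
# ---------------------------------------------------------------------------

def test_nifti_round_trip_preserves_grid_spacing_affine(tmp_path):
    rng = np.random.default_rng(0)
    vol = _vol(rng.normal(size=(8, 8, 8)), spacing=(1.5, 1.5, 1.25))
    path = tmp_path / "v.nii.gz"
    cb.write_volume(vol, path)
    back = cb.read_volume(path)
    np.testing.assert_array_equal(back.data, vol.data)
    np.testing.assert_allclose(back.spacing, (1.5, 1.5, 1.25), atol=1e-6)
    np.testing.assert_allclose(back.affine, vol.affine, atol=1e-6)


def _write_dicom_series(dirpath, data, spacing, order=None):
    """data is (nx, ny, nz); one file per z slice."""
    nx, ny, nz = data.shape
    order = order if order is not None else range(nz)
    series_uid = generate_uid()
    for name_i, z in enumerate(order):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.Modality = "CT"
        ds.Rows, ds.Columns = ny, nx
        ds.PixelSpacing = [str(spacing[1]), str(spacing[0])]
        ds.SliceThickness = str(spacing[2])
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.ImagePositionPatient = [0, 0, float(z) * spacing[2]]
        ds.RescaleSlope, ds.RescaleIntercept = "1", "-1024"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        sl = (data[:, :, z].T + 1024).astype(np.uint16)
        ds.PixelData = sl.tobytes()
        ds.save_as(dirpath / f"slice_{name_i:03d}.dcm", enforce_file_format=True)


def test_dicom_series_reads_hu_and_ignores_file_order(tmp_path):
    rng = np.random.default_rng(1)
    data = np.round(rng.uniform(-100, 100, size=(8, 6, 5)))
    d1 = tmp_path / "sorted"; d1.mkdir()
    d2 = tmp_path / "shuffled"; d2.mkdir()
    _write_dicom_series(d1, data, (1.5, 1.5, 1.25))
    _write_dicom_series(d2, data, (1.5, 1.5, 1.25), order=[3, 0, 4, 1, 2])
    v1 = cb.read_volume(d1, "dicom_series")
    v2 = cb.read_volume(d2, "dicom_series")
    np.testing.assert_array_equal(v1.data, data)      # HU after rescale
    np.testing.assert_array_equal(v2.data, v1.data)   # order invariance
    np.testing.assert_allclose(v1.spacing, (1.5, 1.5, 1.25))


def test_dicom_inconsistent_slice_spacing_rejected(tmp_path):
    data = np.zeros((4, 4, 4))
    d = tmp_path / "bad"; d.mkdir()
    _write_dicom_series(d, data, (1, 1, 1))
    ds = pydicom.dcmread(d / "slice_003.dcm")
    ds.ImagePositionPatient = [0, 0, 7.5]   # gap
    ds.save_as(d / "slice_003.dcm", enforce_file_format=True)
    with pytest.raises(VolumeIOError, match="spacing"):
        cb.read_volume(d, "dicom_series")


def test_missing_file_raises_io_error_naming_path():
    with pytest.raises(VolumeIOError, match="nope.nii"):
        cb.read_volume("nope.nii")


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def test_resample_identity_and_constant():
    rng = np.random.default_rng(2)
    vol = _vol(rng.normal(size=(10, 10, 10)), spacing=(2, 2, 2))
    same = cb.resample_trilinear(vol, (2, 2, 2))
    np.testing.assert_allclose(same.data, vol.data, atol=1e-12)
    const = _vol(np.full((10, 12, 9), 5.0), spacing=(1, 1, 1))
    out = cb.resample_trilinear(const, (1.7, 2.3, 0.9))
    np.testing.assert_allclose(out.data, 5.0, atol=1e-12)


def test_resample_exact_on_linear_ramp():
    # trilinear interpolation reproduces a degree-1 field exactly; voxel
    # centres of the coarse grid sit at old index s*i + (s-1)/2
    n, s = 24, 1.6
    data = np.broadcast_to(np.arange(n, dtype=float)[:, None, None],
                           (n, 6, 6)).copy()
    vol = _vol(data, spacing=(1, 1, 1))
    out = cb.resample_trilinear(vol, (s, 1, 1))
    i = np.arange(out.shape[0], dtype=float)
    expect = np.clip(s * i + (s - 1) / 2, 0, n - 1)
    np.testing.assert_allclose(out.data[:, 2, 3], expect, atol=1e-9)


def test_resample_rejects_labels_and_bad_spacing():
    vol = _vol(np.zeros((8, 8, 8)))
    with pytest.raises(VolumeError):
        cb.resample_trilinear(vol, (1, -1, 1))
    lab = _vol(np.zeros((8, 8, 8)), modality="label")
    with pytest.raises(VolumeError, match="nearest"):
        cb.resample_trilinear(lab, (2, 2, 2))
    out = cb.resample_trilinear(lab, (2, 2, 2), nearest=True)
    assert out.shape == (4, 4, 4)


# ---------------------------------------------------------------------------
# affine application
# ---------------------------------------------------------------------------

def test_apply_affine_identity_and_integer_translation():
    rng = np.random.default_rng(3)
    vol = _vol(rng.normal(size=(9, 9, 9)))
    out = cb.apply_affine(vol, np.eye(4), vol)
    np.testing.assert_allclose(out.data, vol.data, atol=1e-12)

    spike = np.zeros((9, 9, 9)); spike[4, 4, 4] = 1.0
    sv = _vol(spike)
    T = np.eye(4); T[:3, 3] = (2, 0, -1)   # world shift = 2,-0,-1 voxels
    moved = cb.apply_affine(sv, T, sv)
    assert moved.data[6, 4, 3] == pytest.approx(1.0)
    assert moved.data.sum() == pytest.approx(1.0)


def test_apply_affine_inverse_composition_near_identity():
    # smooth analytic volume: residual bounded by interpolation error
    n = 24
    i = np.arange(n)
    X, Y, Z = np.meshgrid(i, i, i, indexing="ij")
    data = np.sin(X / 6.0) * np.cos(Y / 7.0) + 0.1 * Z / n
    vol = _vol(data)
    rng = np.random.default_rng(4)
    T = np.eye(4)
    T[:3, :3] += rng.normal(0, 0.02, (3, 3))
    T[:3, 3] = rng.normal(0, 0.5, 3)
    there = cb.apply_affine(vol, T, vol)
    back = cb.apply_affine(there, np.linalg.inv(T), vol)
    core = (slice(4, -4),) * 3
    assert np.max(np.abs(back.data[core] - vol.data[core])) < 0.02


def test_apply_affine_rejects_singular():
    vol = _vol(np.zeros((4, 4, 4)))
    T = np.eye(4); T[0, 0] = 0.0
    with pytest.raises(VolumeError, match="singular"):
        cb.apply_affine(vol, T, vol)


# ---------------------------------------------------------------------------
# brain masking
# ---------------------------------------------------------------------------

def test_brain_mask_recovers_phantom_interior(small_phantom):
    mask = cb.brain_mask_from_ct(small_phantom.ct, -200, 100)
    truth = small_phantom.mask.mask
    d = cb.dice(mask.mask, truth)
    assert d > 0.97
    assert mask.source == "threshold_morphology"


def test_brain_mask_empty_volume_errors():
    vol = _vol(np.full((20, 20, 20), -1000.0))
    with pytest.raises(VolumeError, match="[Ss]upply"):
        cb.brain_mask_from_ct(vol)


def test_supplied_mask_passthrough():
    m = cb.BrainMask(np.ones((4, 4, 4), bool), source="supplied")
    assert m.source == "supplied"


# ---------------------------------------------------------------------------
# hard labels and ventricular CSF
# ---------------------------------------------------------------------------

def test_hard_labels_argmax_ties_and_mask():
    probs = np.zeros((2, 2, 1, 3))
    probs[0, 0, 0] = (1, 0, 0)            # clear WM
    probs[0, 1, 0] = (1 / 3, 1 / 3, 1 / 3)  # tie -> WM by declared order
    probs[1, 0, 0] = (0.2, 0.5, 0.3)      # GM
    probs[1, 1, 0] = (0, 0, 1)            # CSF but outside mask
    post = cb.PosteriorMap(probs)
    mask = cb.BrainMask(np.array([[[True], [True]], [[True], [False]]]))
    lab = cb.hard_labels(post, mask)
    assert lab.labels[0, 0, 0] == cb.WM
    assert lab.labels[0, 1, 0] == cb.WM
    assert lab.labels[1, 0, 0] == cb.GM
    assert lab.labels[1, 1, 0] == cb.BACKGROUND


def test_hard_labels_inverts_one_hot_posterior(small_phantom):
    truth = small_phantom.truth_labels
    onehot = np.stack([truth.labels == c for c in (1, 2, 3)], axis=3).astype(float)
    # outside-mask rows are all-zero; inside they are exactly one-hot
    post = cb.PosteriorMap(onehot, spacing=truth.spacing, affine=truth.affine)
    lab = cb.hard_labels(post, small_phantom.mask)
    np.testing.assert_array_equal(lab.labels, truth.labels)


def test_ventricular_csf_keeps_interior_blob_only(small_phantom):
    truth = small_phantom.truth_labels
    vent = cb.extract_ventricular_csf(truth, small_phantom.mask.mask)
    got = vent.labels == cb.CSF
    # subset of CSF, nonempty, and excludes the surface film entirely
    csf = truth.labels == cb.CSF
    assert got.any() and (got <= csf).all()
    surface = small_phantom.mask.mask & ~ndimage.binary_erosion(
        small_phantom.mask.mask)
    assert not (got & surface).any()


def test_ventricular_csf_no_csf_warns():
    lab = cb.LabelMap(np.ones((6, 6, 6)))
    with pytest.warns(UserWarning, match="no CSF"):
        out = cb.extract_ventricular_csf(lab)
    assert not (out.labels == cb.CSF).any()


def test_ventricular_csf_all_interior_identity():
    labels = np.ones((12, 12, 12), dtype=np.uint8)  # WM mask everywhere
    labels[5:8, 5:8, 5:8] = cb.CSF
    lab = cb.LabelMap(labels)
    out = cb.extract_ventricular_csf(lab)
    np.testing.assert_array_equal(out.labels == cb.CSF, labels == cb.CSF)
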