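"""Volumetric image containers and grid operations.

All volumes are 3D scalar grids with a voxel spacing (mm per axis) and a
4x4 voxel-index -> world-mm affine.  CT intensities are in Hounsfield
units; probability maps are in [0, 1]; label maps use the fixed code set
0 = background, 1 = white matter, 2 = gray matter, 3 = CSF.  All distance
computations downstream are carried out in world millimetres.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom
from scipy import ndimage

log = logging.getLogger(__name__)

BACKGROUND, WM, GM, CSF = 0, 1, 2, 3
TISSUE_CLASSES = ("wm", "gm", "csf")
LABEL_CODES = {"background": BACKGROUND, "wm": WM, "gm": GM, "csf": CSF}


class VolumeError(ValueError):
    """Raised on contract violations of volume operations."""


class VolumeIOError(IOError):
    """Raised when a volume file cannot be read or parsed."""


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise VolumeError(f"affine must be 4x4, got {affine.shape}")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise VolumeError("affine is singular")
    return affine


@dataclass
class ImageVolume:
    """A 3D scalar grid plus geometry.

    Parameters
    ----------
    data : (nx, ny, nz) array
    spacing : mm per axis, strictly positive
    affine : 4x4 voxel-index -> world-mm map
    modality : one of ``{"ct", "probability", "label"}``
    """

    data: np.ndarray
    spacing: tuple
    affine: np.ndarray
    modality: str = "ct"

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise VolumeError("data must be a 3D grid with >=1 voxel per axis")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise VolumeError(f"spacing must be 3 positive reals, got {self.spacing}")
        self.affine = _check_affine(self.affine)
        if self.modality not in ("ct", "probability", "label"):
            raise VolumeError(f"unknown modality {self.modality!r}")
        if self.modality == "probability":
            lo, hi = float(np.min(self.data)), float(np.max(self.data))
            if lo < -1e-6 or hi > 1 + 1e-6:
                raise VolumeError(
                    f"probability volume values outside [0,1]: range [{lo}, {hi}]"
                )

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def world_coords(self, centered: bool = False) -> np.ndarray:
        """Voxel-centre world coordinates, shape (3, nx, ny, nz), in mm.

        With ``centered=True`` coordinates are relative to the world
        position of the grid centre.
        """
        idx = np.indices(self.shape, dtype=float)
        R, t = self.affine[:3, :3], self.affine[:3, 3]
        xyz = np.einsum("ij,j...->i...", R, idx) + t[:, None, None, None]
        if centered:
            centre_idx = (np.asarray(self.shape, float) - 1.0) / 2.0
            xyz -= (R @ centre_idx + t)[:, None, None, None]
        return xyz

    def with_data(self, data: np.ndarray, modality: str | None = None) -> "ImageVolume":
        return ImageVolume(data, self.spacing, self.affine.copy(),
                           modality or self.modality)


@dataclass
class BrainMask:
    """Boolean intracranial mask tied to a parent grid."""

    mask: np.ndarray
    source: str = "threshold_morphology"  # or "supplied"

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise VolumeError("mask must be 3D")
        if self.source not in ("supplied", "threshold_morphology"):
            raise VolumeError(f"unknown mask source {self.source!r}")

    @property
    def shape(self):
        return self.mask.shape


@dataclass
class LabelMap:
    """Hard tissue labels: 0 background, 1 WM, 2 GM, 3 CSF."""

    labels: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.isin(self.labels, [BACKGROUND, WM, GM, CSF]).all():
            raise VolumeError("label codes restricted to {0,1,2,3}")
        self.labels = self.labels.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.affine = _check_affine(self.affine)

    @property
    def shape(self):
        return self.labels.shape

    def class_mask(self, code: int) -> np.ndarray:
        return self.labels == code


@dataclass
class PosteriorMap:
    """Per-voxel class posterior probabilities, shape (nx, ny, nz, K)."""

    probs: np.ndarray
    class_names: tuple = TISSUE_CLASSES
    spacing: tuple = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 4:
            raise VolumeError("posterior probs must be 4D (3 spatial + class)")
        if self.probs.min() < -1e-9 or self.probs.max() > 1 + 1e-9:
            raise VolumeError("posterior values outside [0,1]")
        if self.probs.shape[3] != len(self.class_names):
            raise VolumeError("class axis length must match class_names")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.affine = _check_affine(self.affine)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_volume(path, format: str | None = None, modality: str = "ct") -> ImageVolume:
    """Read a NIfTI file or a DICOM series directory into an ImageVolume.

    ``format`` is one of ``{"nifti", "dicom_series"}``; when omitted it is
    inferred (directories are treated as DICOM series).  DICOM slices are
    sorted by their position along the slice normal, so file order on disk
    is irrelevant.
    """
    path = Path(path)
    if not path.exists():
        raise VolumeIOError(f"no such file or directory: {path}")
    if format is None:
        format = "dicom_series" if path.is_dir() else "nifti"
    if format == "nifti":
        try:
            img = nib.load(str(path))
            data = np.asarray(img.dataobj, dtype=np.float64)
        except Exception as exc:  # nibabel raises a zoo of types
            raise VolumeIOError(f"cannot read NIfTI file {path}: {exc}") from exc
        if data.ndim == 4 and data.shape[3] == 1:
            data = data[..., 0]
        if data.ndim != 3:
            raise VolumeIOError(f"{path}: expected a 3D volume, got shape {data.shape}")
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return ImageVolume(data, spacing, np.asarray(img.affine), modality)
    if format == "dicom_series":
        return _read_dicom_series(path, modality)
    raise VolumeError(f"unknown format {format!r}")


def _read_dicom_series(path: Path, modality: str) -> ImageVolume:
    files = sorted(p for p in path.iterdir() if p.is_file())
    if not files:
        raise VolumeIOError(f"no files in DICOM directory {path}")
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception as exc:
            raise VolumeIOError(f"cannot parse DICOM file {f}: {exc}") from exc
        slices.append(ds)
    orient = np.array(slices[0].ImageOrientationPatient, dtype=float)
    row, col = orient[:3], orient[3:]
    normal = np.cross(row, col)
    pos = [float(np.dot(normal, np.array(s.ImagePositionPatient, float))) for s in slices]
    order = np.argsort(pos)
    slices = [slices[i] for i in order]
    pos = sorted(pos)
    if len(slices) > 1:
        dz = np.diff(pos)
        if dz.min() <= 0 or (dz.max() - dz.min()) > 1e-3 * dz.mean() + 1e-6:
            raise VolumeIOError(
                f"inconsistent DICOM slice spacing in {path}: steps {dz.min():.4g}"
                f"..{dz.max():.4g} mm"
            )
        slice_step = float(dz.mean())
    else:
        slice_step = float(getattr(slices[0], "SliceThickness", 1.0))
    dr, dc = (float(x) for x in slices[0].PixelSpacing)
    arrays = []
    for s in slices:
        a = s.pixel_array.astype(np.float64)
        slope = float(getattr(s, "RescaleSlope", 1.0))
        inter = float(getattr(s, "RescaleIntercept", 0.0))
        arrays.append(a * slope + inter)
    # DICOM pixel arrays are (rows, cols); build (col, row, slice) so that
    # axis order matches (x, y, z) under the orientation vectors.
    data = np.stack([a.T for a in arrays], axis=2)
    affine = np.eye(4)
    affine[:3, 0] = col * dc
    affine[:3, 1] = row * dr
    affine[:3, 2] = normal * slice_step
    affine[:3, 3] = np.array(slices[0].ImagePositionPatient, float)
    return ImageVolume(data, (dc, dr, slice_step), affine, modality)


def write_volume(vol, path) -> None:
    """Write an ImageVolume / LabelMap / PosteriorMap as NIfTI-1.

    Label maps additionally get a JSON sidecar with the label-code mapping.
    """
    path = Path(path)
    if isinstance(vol, LabelMap):
        img = nib.Nifti1Image(vol.labels.astype(np.int16), vol.affine)
        img.header.set_zooms(vol.spacing)
        nib.save(img, str(path))
        side = path.with_suffix("").with_suffix("")  # strip .nii.gz / .nii
        with open(str(side) + "_labels.json", "w") as fh:
            json.dump(LABEL_CODES, fh, indent=2)
        return
    if isinstance(vol, PosteriorMap):
        img = nib.Nifti1Image(vol.probs.astype(np.float32), vol.affine)
        img.header.set_zooms(tuple(vol.spacing) + (1.0,))
        nib.save(img, str(path))
        return
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float64), vol.affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def read_label_map(path) -> LabelMap:
    vol = read_volume(path, "nifti", modality="label")
    return LabelMap(np.rint(vol.data).astype(np.uint8), vol.spacing, vol.affine)


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def resample_trilinear(vol: ImageVolume, target_spacing, nearest: bool = False
                       ) -> ImageVolume:
    """Resample a volume to a new voxel spacing over the same world extent.

    Intensity and probability volumes use trilinear interpolation; label
    volumes are rejected unless ``nearest=True`` requests nearest-neighbour
    interpolation (prevents label mixing).
    """
    target_spacing = tuple(float(s) for s in target_spacing)
    if any(s <= 0 for s in target_spacing):
        raise VolumeError(f"target spacing must be positive, got {target_spacing}")
    if vol.modality == "label" and not nearest:
        raise VolumeError("label volumes must be resampled with nearest=True")
    scale = np.array([t / s for t, s in zip(target_spacing, vol.spacing)])
    new_shape = tuple(max(1, int(round(n / f))) for n, f in zip(vol.shape, scale))
    # pixel-edge alignment: new index i maps to old index scale*i + (scale-1)/2
    grids = np.indices(new_shape, dtype=float)
    coords = [scale[d] * grids[d] + (scale[d] - 1.0) / 2.0 for d in range(3)]
    order = 0 if nearest else 1
    data = ndimage.map_coordinates(np.asarray(vol.data, float), coords,
                                   order=order, mode="nearest")
    S = np.eye(4)
    S[:3, :3] = np.diag(scale)
    S[:3, 3] = (scale - 1.0) / 2.0
    return ImageVolume(data, target_spacing, vol.affine @ S, vol.modality)


def _as_affine44(affine12) -> np.ndarray:
    a = np.asarray(affine12, dtype=float)
    if a.shape == (4, 4):
        T = a
    elif a.size == 12:
        T = np.eye(4)
        T[:3, :4] = a.reshape(3, 4)
    else:
        raise VolumeError("affine must be 4x4 or 12 parameters (3x4)")
    if abs(np.linalg.det(T[:3, :3])) < 1e-12:
        raise VolumeError("affine transform is singular")
    return T


def apply_affine(vol: ImageVolume, affine12, reference: ImageVolume) -> ImageVolume:
    """Resample ``vol`` onto the grid of ``reference`` under a world-space
    affine transform mapping vol-world to reference-world coordinates.

    Trilinear interpolation for intensities/probabilities, nearest-neighbour
    for labels.  Only *application* of a given (e.g. 12-parameter) transform
    is provided; estimating it is out of scope.
    """
    T = _as_affine44(affine12)
    M = np.linalg.inv(vol.affine) @ np.linalg.inv(T) @ reference.affine
    grids = np.indices(reference.shape, dtype=float)
    idx = np.stack([grids[0], grids[1], grids[2], np.ones(reference.shape)])
    src = np.einsum("ij,j...->i...", M, idx)[:3]
    order = 0 if vol.modality == "label" else 1
    data = ndimage.map_coordinates(np.asarray(vol.data, float), src,
                                   order=order, mode="nearest")
    return ImageVolume(data, reference.spacing, reference.affine.copy(), vol.modality)


def resample_to_grid(vol: ImageVolume, reference: ImageVolume) -> ImageVolume:
    """Resample ``vol`` onto the grid of ``reference`` (identity world map)."""
    return apply_affine(vol, np.eye(4), reference)


# ---------------------------------------------------------------------------
# Brain masking and label utilities
# ---------------------------------------------------------------------------

def brain_mask_from_ct(vol: ImageVolume, low_hu: float = -200.0,
                       high_hu: float = 100.0, opening_radius: int = 2
                       ) -> BrainMask:
    """Deterministic intracranial mask from a CT volume.

    Thresholds to (low_hu, high_hu), applies morphological opening, keeps
    the largest connected component and fills holes.  The defaults exclude
    air (~ -1000 HU) and bone (>~ 700 HU) at typical head-CT radiodensities.
    A user-supplied mask always takes precedence over this heuristic.
    """
    if vol.modality != "ct":
        raise VolumeError("brain_mask_from_ct requires a CT-modality volume")
    raw = (vol.data > low_hu) & (vol.data < high_hu)
    if opening_radius > 0:
        ball = _ball(opening_radius)
        raw = ndimage.binary_opening(raw, structure=ball)
    lab, n = ndimage.label(raw)
    if n == 0:
        raise VolumeError(
            "brain mask is empty after thresholding/morphology; "
            "supply an external mask instead"
        )
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    mask = lab == (1 + int(np.argmax(sizes)))
    mask = ndimage.binary_fill_holes(mask)
    return BrainMask(mask, source="threshold_morphology")


def _ball(radius: int) -> np.ndarray:
    r = int(radius)
    z, y, x = np.mgrid[-r:r + 1, -r:r + 1, -r:r + 1]
    return x * x + y * y + z * z <= r * r


def interior_mask(mask, margin_voxels: int = 4) -> np.ndarray:
    """Erode a mask by a safety margin; the 'interior' domain used when a
    statistic should not be dominated by brain-edge effects."""
    m = mask.mask if isinstance(mask, BrainMask) else np.asarray(mask, bool)
    out = ndimage.binary_erosion(m, iterations=int(margin_voxels))
    return out if out.any() else m


def hard_labels(post: PosteriorMap, mask: BrainMask) -> LabelMap:
    """Argmax class assignment inside the mask, background outside.

    Ties are broken by the fixed class order WM < GM < CSF (``np.argmax``
    returns the first maximal index and the class axis is ordered so).
    """
    if post.probs.shape[:3] != mask.shape:
        raise VolumeError("posterior and mask grids differ")
    arg = np.argmax(post.probs, axis=3).astype(np.uint8) + 1
    labels = np.where(mask.mask, arg, np.uint8(BACKGROUND))
    return LabelMap(labels, post.spacing, post.affine)


def extract_ventricular_csf(labels: LabelMap, mask: np.ndarray | None = None
                            ) -> LabelMap:
    """Keep only interior CSF connected components (ventricular proxy).

    CSF components (26-connectivity) touching the brain-mask boundary —
    i.e. the outermost mask layer — are discarded; what remains is the
    ventricular-CSF stand-in used for cross-modality CSF comparison.
    """
    if mask is None:
        mask = labels.labels != BACKGROUND
    csf = labels.class_mask(CSF)
    out = np.zeros_like(labels.labels)
    if not csf.any():
        warnings.warn("label map contains no CSF; ventricular CSF is empty")
        return LabelMap(out, labels.spacing, labels.affine)
    boundary_layer = mask & ~ndimage.binary_erosion(mask)
    comp, n = ndimage.label(csf, structure=np.ones((3, 3, 3), dtype=bool))
    touches = np.unique(comp[boundary_layer & (comp > 0)])
    keep = np.isin(comp, np.setdiff1d(np.arange(1, n + 1), touches)) & (comp > 0)
    if not keep.any():
        warnings.warn("no interior CSF component found; ventricular CSF is empty")
    out[keep] = CSF
    return LabelMap(out, labels.spacing, labels.affine)
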