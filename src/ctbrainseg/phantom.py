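"""Synthetic head-CT phantom with matched atlas and known deformation.

The phantom emulates the gross geometry and radiodensity structure of a
head CT: an ellipsoidal white-matter core whose surface carries low-order
sinusoidal, gyrus-like undulations, a cortical gray-matter shell, a pair
of interior CSF "ventricles", a thin surface CSF film, a bone shell
(1000 HU) and surrounding air (-1000 HU).  Class intensities are Gaussian
in HU; the GM/WM means default to published standard-dose head-CT
radiodensities (GM 38.7 +/- 2.2 HU, WM 31.8 +/- 2.3 HU); CSF defaults to
8 +/- 3 HU, inside the clinically typical 0-15 HU range.

Every phantom also carries a known smooth deformation drawn in the same
sine basis the segmentation fitter uses, so atlas-misalignment recovery
is a well-posed test; :func:`make_synthetic_atlas` builds the matching
imperfect prior atlas (smoothed truth, warped *against* the stored
deformation so that fitting recovers it with positive sign).

All outputs are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage

from .priors import (DeformationParams, SineBasis, TissuePriorAtlas,
                     displacement_field, warp_priors)
from .volumes import (CSF, GM, WM, BrainMask, ImageVolume, LabelMap,
                      TISSUE_CLASSES, VolumeError)

FWHM_TO_SIGMA = 1.0 / 2.35482


@dataclass
class PhantomSpec:
    """Geometry, intensity and deformation parameters of the phantom."""

    grid_shape: tuple = (64, 64, 64)
    spacing: tuple = (1.5, 1.5, 1.25)          # mm; concussed-group CT grid
    class_means: dict = dc_field(default_factory=lambda: {
        "wm": 31.8, "gm": 38.7, "csf": 8.0})   # HU
    class_sds: dict = dc_field(default_factory=lambda: {
        "wm": 2.3, "gm": 2.2, "csf": 3.0})     # HU
    noise_sd: float = 1.0                      # HU, extra global noise
    brain_radii_mm: tuple = (36.0, 36.0, 30.0)  # ellipsoid semi-axes cap
    ventricle_radius_mm: float = 6.0
    cortical_thickness_mm: float = 5.0
    csf_film_mm: float = 2.0
    bone_thickness_mm: float = 3.0
    gyral_amplitude: float = 0.12              # fractional WM-radius undulation
    deformation_amplitude: float = 2.0         # mm, max |u| of truth field
    deformation_freqs: tuple = (3, 3, 3)
    seed: int = 0

    def __post_init__(self):
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        if min(self.grid_shape) < 16:
            raise VolumeError("phantom grid must be >= 16 voxels per axis")
        if any(sd < 0 for sd in self.class_sds.values()) or self.noise_sd < 0:
            raise VolumeError("intensity SDs must be nonnegative")


@dataclass
class PhantomResult:
    ct: ImageVolume
    truth_labels: LabelMap
    truth_priors: TissuePriorAtlas
    truth_deformation: DeformationParams
    mask: BrainMask


def _affine(spec: PhantomSpec) -> np.ndarray:
    A = np.eye(4)
    A[:3, :3] = np.diag(spec.spacing)
    A[:3, 3] = -0.5 * (np.asarray(spec.grid_shape) - 1) * np.asarray(spec.spacing)
    return A


def make_head_phantom(spec: PhantomSpec) -> PhantomResult:
    """Generate the phantom CT, truth labels, one-hot priors, mask and a
    known sine-basis deformation, all reproducible from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    shape = spec.grid_shape
    sp = np.asarray(spec.spacing, float)
    extent = (np.asarray(shape) - 1) * sp
    centre = extent / 2.0
    idx = np.indices(shape, dtype=float)
    x = idx[0] * sp[0] - centre[0]
    y = idx[1] * sp[1] - centre[1]
    z = idx[2] * sp[2] - centre[2]

    brain_r = np.minimum(extent / 2.0 - spec.bone_thickness_mm - 2.0 * sp,
                         np.asarray(spec.brain_radii_mm, float))
    if np.any(brain_r <= spec.cortical_thickness_mm + spec.csf_film_mm + 4.0):
        raise VolumeError("grid too small for the requested phantom geometry")
    skull_r = brain_r + spec.bone_thickness_mm
    gm_outer_r = brain_r - spec.csf_film_mm
    wm_r = gm_outer_r - spec.cortical_thickness_mm
    if np.any(wm_r <= spec.ventricle_radius_mm + 2.0):
        raise VolumeError("ventricle_radius_mm too large for the WM core")

    def rho(radii):
        return np.sqrt((x / radii[0]) ** 2 + (y / radii[1]) ** 2
                       + (z / radii[2]) ** 2)

    # gyrus-like undulation of the WM surface (low-order sinusoidal)
    und = (np.sin(2 * np.pi * x / 30.0) * np.sin(2 * np.pi * y / 30.0)
           * np.cos(2 * np.pi * z / 40.0))
    labels = np.zeros(shape, dtype=np.uint8)
    in_skull = rho(skull_r) < 1.0
    in_brain = rho(brain_r) < 1.0
    in_gm = rho(gm_outer_r) < 1.0
    in_wm = rho(wm_r) < 1.0 + spec.gyral_amplitude * und
    vent_off = np.array([spec.ventricle_radius_mm + 2.0, 0.0, 0.0])
    vr = spec.ventricle_radius_mm
    in_vent = np.zeros(shape, dtype=bool)
    for sgn in (-1.0, 1.0):
        in_vent |= ((x - sgn * vent_off[0]) ** 2 + y ** 2 + z ** 2) < vr ** 2

    BONE, AIR = 4, 5  # internal geometry codes, never emitted in labels
    geo = np.full(shape, AIR, dtype=np.uint8)
    geo[in_skull] = BONE
    geo[in_brain] = CSF
    geo[in_gm] = GM
    geo[in_wm & in_gm] = WM
    geo[in_vent] = CSF

    brain = np.isin(geo, (WM, GM, CSF))
    labels[brain] = geo[brain]

    ct = np.empty(shape, dtype=float)
    ct[geo == AIR] = -1000.0
    ct[geo == BONE] = 1000.0
    for name, code in zip(TISSUE_CLASSES, (WM, GM, CSF)):
        sel = geo == code
        ct[sel] = spec.class_means[name]
        if spec.class_sds[name] > 0:
            ct[sel] += rng.normal(0.0, spec.class_sds[name], int(sel.sum()))
    if spec.noise_sd > 0:
        ct += rng.normal(0.0, spec.noise_sd, shape)

    # one-hot partition of unity over wm/gm/csf/background
    onehot = np.stack([labels == WM, labels == GM, labels == CSF, ~brain],
                      axis=3).astype(float)
    aff = _affine(spec)
    truth_priors = TissuePriorAtlas(onehot, TISSUE_CLASSES + ("background",),
                                    spec.spacing, aff)

    # known smooth deformation inside the fitter's basis family
    basis = SineBasis(shape, spec.deformation_freqs)
    alpha = rng.standard_normal((3,) + tuple(spec.deformation_freqs))
    m1, m2, m3 = np.meshgrid(*[np.arange(1, n + 1) for n in spec.deformation_freqs],
                             indexing="ij")
    alpha /= (m1 ** 2 + m2 ** 2 + m3 ** 2)  # favour the lowest modes
    dparams = DeformationParams(alpha)
    if spec.deformation_amplitude > 0:
        fld = displacement_field(dparams, basis, (shape, spec.spacing))
        peak = float(np.abs(fld).max())
        if peak > 0:
            dparams = DeformationParams(alpha * spec.deformation_amplitude / peak)
    else:
        dparams = DeformationParams(np.zeros_like(alpha))

    ct_vol = ImageVolume(ct, spec.spacing, aff, "ct")
    return PhantomResult(
        ct=ct_vol,
        truth_labels=LabelMap(labels, spec.spacing, aff),
        truth_priors=truth_priors,
        truth_deformation=dparams,
        mask=BrainMask(brain, source="threshold_morphology"),
    )


def make_cohort_spec(seed: int, grid_shape=(48, 48, 48),
                     spacing=(1.5, 1.5, 1.25)) -> PhantomSpec:
    """Per-subject phantom spec with seeded anatomical variability.

    Subjects of a synthetic cohort differ in brain size, ventricle size
    and cortical thickness (drawn once per seed), so between-subject
    volume variance is realistic and cohort statistics such as the
    intraclass correlation are well defined.
    """
    rng = np.random.default_rng(seed)
    extent = (np.asarray(grid_shape) - 1) * np.asarray(spacing, float)
    cap = extent / 2.0 - 3.0 - 2.0 * np.asarray(spacing, float)
    radii = tuple(cap * rng.uniform(0.82, 1.0, 3))
    return PhantomSpec(
        grid_shape=tuple(grid_shape), spacing=tuple(spacing),
        brain_radii_mm=radii,
        ventricle_radius_mm=float(rng.uniform(4.5, 6.5)),
        cortical_thickness_mm=float(rng.uniform(4.0, 6.0)),
        seed=seed,
    )


def make_synthetic_atlas(result: PhantomResult, blur_fwhm_mm: float = 4.0,
                         misalign: DeformationParams | None = None
                         ) -> TissuePriorAtlas:
    """Imperfect prior atlas: smoothed one-hot truth, misaligned.

    The one-hot truth labels are blurred with a Gaussian of the stated
    FWHM, renormalized to sum to 1 where their sum exceeds 1, then warped
    by the *negative* of ``misalign`` (default: the phantom's stored truth
    deformation).  Sampling the result at x + u(x) — what the segmentation
    fitter does with the recovered field u — then restores alignment with
    the subject, so recovery tests compare the fitted field directly to
    the truth field.  With ``blur_fwhm_mm = 0`` and a zero misalignment the
    atlas is exactly the one-hot truth.
    """
    if blur_fwhm_mm < 0:
        raise VolumeError("blur_fwhm_mm must be >= 0")
    truth = result.truth_priors
    if misalign is None:
        misalign = result.truth_deformation
    P = truth.priors.copy()
    if blur_fwhm_mm > 0:
        sig = [blur_fwhm_mm * FWHM_TO_SIGMA / s for s in truth.spacing]
        for c in range(P.shape[3]):
            P[..., c] = ndimage.gaussian_filter(P[..., c], sigma=sig)
        # blurring a partition of unity preserves it; the floor keeps every
        # class representable, and renormalizing restores the unit sum
        P += 1e-4
        P /= P.sum(axis=3, keepdims=True)
    atlas = TissuePriorAtlas(np.clip(P, 0, 1), truth.class_names,
                             truth.spacing, truth.affine.copy())
    if np.any(misalign.alpha != 0) or np.any(misalign.scale != 1):
        basis = SineBasis(truth.grid_shape, misalign.freqs)
        fld = displacement_field(misalign, basis, (truth.grid_shape, truth.spacing))
        atlas = warp_priors(atlas, -fld)
    return atlas


def ablate_contrast(ct: ImageVolume, mask: BrainMask, seed: int) -> ImageVolume:
    """Destroy within-brain tissue contrast (control experiment).

    The mean and SD of all within-mask intensities are computed, and every
    within-mask voxel is replaced by an i.i.d. draw from that single
    Gaussian; voxels outside the mask are untouched.  Segmenting the
    result probes how much of the segmentation is driven by the priors
    alone rather than by tissue radiodensity.
    """
    if not mask.mask.any():
        raise VolumeError("ablate_contrast requires a nonempty mask")
    rng = np.random.default_rng(seed)
    vals = ct.data[mask.mask]
    mu, sd = float(vals.mean()), float(vals.std())
    out = np.array(ct.data, dtype=float, copy=True)
    out[mask.mask] = rng.normal(mu, sd, int(mask.mask.sum()))
    return ct.with_data(out)
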