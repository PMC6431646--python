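"""Deformable spatial priors for atlas-guided tissue classification.

A tissue-prior atlas supplies, for every voxel i and tissue class k, a
prior probability P_ik.  Combined with the mixture's mixing coefficients
gamma_k, the per-voxel prior weight of cluster k is

    w_ik = gamma_k P_ik / sum_j gamma_j P_ij .

To absorb residual atlas-to-subject misregistration the priors are warped
by a smooth displacement field parameterized in a low-frequency discrete
sine basis (separable products of the lowest sine modes per axis), plus
three linear scaling parameters and one linear intensity-inhomogeneity
coefficient.  The sine coefficients carry a zero-mean Gaussian prior with
diagonal covariance C_alpha, which acts as a bending-energy-like
regularizer (higher frequencies are penalized more).

Displacements are expressed in millimetres along the grid axes, relative
to the grid centre; for the axis-aligned affines used throughout this
package that coincides with world mm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volumes import ImageVolume, VolumeError, _check_affine

log = logging.getLogger(__name__)


class PriorError(ValueError):
    pass


@dataclass
class TissuePriorAtlas:
    """Stacked per-class prior probability maps, shape (nx, ny, nz, C)."""

    priors: np.ndarray
    class_names: tuple
    spacing: tuple = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.priors = np.asarray(self.priors, float)
        if self.priors.ndim != 4:
            raise PriorError("atlas priors must be 4D (3 spatial + class)")
        if self.priors.min() < -1e-9 or self.priors.max() > 1 + 1e-9:
            raise PriorError("atlas prior values must lie in [0,1]")
        self.priors = np.clip(self.priors, 0.0, 1.0)
        if self.priors.shape[3] != len(self.class_names):
            raise PriorError("class axis length must match class_names")
        for c, name in enumerate(self.class_names):
            if not (self.priors[..., c] > 0).any():
                raise PriorError(f"atlas class {name!r} is nowhere positive")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.affine = _check_affine(self.affine)

    @property
    def grid_shape(self):
        return self.priors.shape[:3]

    @property
    def n_classes(self):
        return self.priors.shape[3]

    def class_index(self, name: str) -> int:
        return self.class_names.index(name)


class SineBasis:
    """Separable 3D discrete-sine basis on a voxel grid.

    Mode (m1, m2, m3), m_d = 1..n_d, evaluates at voxel index (i, j, k) as
    sin(pi m1 i/(N1-1)) sin(pi m2 j/(N2-1)) sin(pi m3 k/(N3-1)); every mode
    vanishes on the grid boundary faces and the columns are mutually
    orthogonal on the grid.
    """

    def __init__(self, grid_shape, freqs):
        self.grid_shape = tuple(int(n) for n in grid_shape)
        self.freqs = tuple(int(n) for n in freqs)
        if len(self.freqs) != 3:
            raise PriorError("freqs must be a triple")
        self.factors = []
        for N, n in zip(self.grid_shape, self.freqs):
            if n < 1 or n > N - 2:
                raise PriorError(
                    f"frequency count {n} invalid for axis of length {N} "
                    f"(need 1 <= n <= {N - 2})"
                )
            i = np.arange(N, dtype=float)
            m = np.arange(1, n + 1, dtype=float)
            F = np.sin(np.pi * np.outer(i, m) / (N - 1))
            F[-1, :] = 0.0  # sin(pi m) exactly, not to rounding
            self.factors.append(F)

    @property
    def n_modes(self) -> int:
        return int(np.prod(self.freqs))

    def matrix(self) -> np.ndarray:
        """Dense (I, n1*n2*n3) basis matrix; voxels in C order."""
        Sx, Sy, Sz = self.factors
        full = np.einsum("xa,yb,zc->xyzabc", Sx, Sy, Sz)
        return full.reshape(np.prod(self.grid_shape), self.n_modes)

    def field(self, alpha: np.ndarray) -> np.ndarray:
        """Scalar field sum_m alpha_m phi_m on the grid, shape grid_shape."""
        alpha = np.asarray(alpha, float).reshape(self.freqs)
        Sx, Sy, Sz = self.factors
        return np.einsum("xa,yb,zc,abc->xyz", Sx, Sy, Sz, alpha)

    def contract(self, v: np.ndarray) -> np.ndarray:
        """Phi^T v for a full-grid scalar field v, shape freqs."""
        Sx, Sy, Sz = self.factors
        return np.einsum("xyz,xa,yb,zc->abc", v, Sx, Sy, Sz)

    def weighted_gram(self, w: np.ndarray) -> np.ndarray:
        """Phi^T diag(w) Phi for a full-grid weight field, shape (M, M)."""
        Sx, Sy, Sz = self.factors
        G = np.einsum("xyz,xa,yb,zc,xd,ye,zf->abcdef", w, Sx, Sy, Sz,
                      Sx, Sy, Sz, optimize=True)
        M = self.n_modes
        return G.reshape(M, M)


def sine_basis(grid_shape, freqs) -> SineBasis:
    """Construct the low-frequency discrete-sine deformation basis."""
    return SineBasis(grid_shape, freqs)


@dataclass
class DeformationParams:
    """Sine-basis deformation coefficients plus linear scaling and a
    linear intensity-inhomogeneity coefficient.

    ``alpha`` has shape (3, n1, n2, n3): one coefficient block per spatial
    axis, in mm.  ``scale`` are the three linear scaling factors (unity =
    no scaling); ``inhomog`` is the dimensionless axial gain coefficient.
    """

    alpha: np.ndarray
    scale: np.ndarray = field(default_factory=lambda: np.ones(3))
    inhomog: float = 0.0

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, float)
        if self.alpha.ndim != 4 or self.alpha.shape[0] != 3:
            raise PriorError("alpha must have shape (3, n1, n2, n3)")
        self.scale = np.asarray(self.scale, float)
        if self.scale.shape != (3,):
            raise PriorError("scale must have 3 entries")
        if not (np.all(np.isfinite(self.alpha)) and np.all(np.isfinite(self.scale))
                and np.isfinite(self.inhomog)):
            raise PriorError("deformation parameters must be finite")
        self.inhomog = float(self.inhomog)

    @classmethod
    def zero(cls, freqs) -> "DeformationParams":
        return cls(np.zeros((3,) + tuple(freqs)))

    @property
    def freqs(self):
        return self.alpha.shape[1:]

    def copy(self) -> "DeformationParams":
        return DeformationParams(self.alpha.copy(), self.scale.copy(), self.inhomog)

    def to_dict(self) -> dict:
        return {"alpha": self.alpha.tolist(), "scale": self.scale.tolist(),
                "inhomog": self.inhomog}

    @classmethod
    def from_dict(cls, d: dict) -> "DeformationParams":
        return cls(np.asarray(d["alpha"]), np.asarray(d["scale"]), d["inhomog"])


@dataclass
class RegularizationConfig:
    """Gaussian prior on the sine coefficients.

    The diagonal covariance defaults to c_base on the lowest mode and
    decays as 1/(m1^2+m2^2+m3^2)^2 — a weakly informative, bending-energy
    style prior that damps high-frequency deformation.
    """

    basis_freqs: tuple = (7, 3, 8)
    c_base: float = 0.5
    c_alpha: np.ndarray = None
    scale_prior_sd: float = 0.05  # Gaussian prior SD on (scale - 1)

    def __post_init__(self):
        self.basis_freqs = tuple(int(n) for n in self.basis_freqs)
        if self.c_alpha is None:
            m1, m2, m3 = np.meshgrid(*[np.arange(1, n + 1) for n in self.basis_freqs],
                                     indexing="ij")
            f2 = (m1 ** 2 + m2 ** 2 + m3 ** 2).astype(float)
            self.c_alpha = self.c_base * 9.0 / f2 ** 2
        self.c_alpha = np.asarray(self.c_alpha, float)
        if self.c_alpha.shape != self.basis_freqs:
            raise PriorError("c_alpha shape must match basis_freqs")
        if np.any(self.c_alpha <= 0):
            raise PriorError("c_alpha diagonal entries must be positive")


def centered_coords_mm(shape, spacing) -> np.ndarray:
    """Axis-aligned voxel-centre coordinates in mm relative to the grid
    centre, shape (3, nx, ny, nz)."""
    idx = np.indices(shape, dtype=float)
    centre = (np.asarray(shape, float) - 1.0) / 2.0
    sp = np.asarray(spacing, float)
    return (idx - centre[:, None, None, None]) * sp[:, None, None, None]


def displacement_field(params: DeformationParams, basis: SineBasis,
                       grid) -> np.ndarray:
    """Evaluate the displacement field in mm, shape (3, nx, ny, nz).

    Component d is  basis . alpha_d  +  (scale_d - 1) x_d,  with x_d the
    centred axis coordinate in mm (scaling is about the grid centre).
    ``grid`` is an ImageVolume, TissuePriorAtlas, or (shape, spacing) pair.
    """
    if isinstance(grid, ImageVolume):
        shape, spacing = grid.shape, grid.spacing
    elif isinstance(grid, TissuePriorAtlas):
        shape, spacing = grid.grid_shape, grid.spacing
    else:
        shape, spacing = grid
    if tuple(shape) != basis.grid_shape:
        raise PriorError("grid shape does not match basis grid")
    coords = centered_coords_mm(shape, spacing)
    out = np.empty((3,) + tuple(shape))
    for d in range(3):
        out[d] = basis.field(params.alpha[d]) + (params.scale[d] - 1.0) * coords[d]
    return out


def warp_priors(atlas: TissuePriorAtlas, field_mm: np.ndarray) -> TissuePriorAtlas:
    """Resample each class map at x + u(x) (backward mapping).

    Trilinear interpolation; samples falling outside the grid take the
    atlas boundary value.  Voxels whose warped class sum exceeds 1 are
    renormalized (interpolation can slightly inflate the sum).
    """
    field_mm = np.asarray(field_mm, float)
    if not np.all(np.isfinite(field_mm)):
        raise PriorError("displacement field must be finite")
    shape = atlas.grid_shape
    idx = np.indices(shape, dtype=float)
    sp = np.asarray(atlas.spacing, float)
    coords = idx + field_mm / sp[:, None, None, None]
    warped = np.empty_like(atlas.priors)
    for c in range(atlas.n_classes):
        warped[..., c] = ndimage.map_coordinates(atlas.priors[..., c], coords,
                                                 order=1, mode="nearest")
    warped = np.clip(warped, 0.0, 1.0)
    s = warped.sum(axis=3)
    over = s > 1.0
    if over.any():
        warped[over] /= s[over][:, None]
    return TissuePriorAtlas(warped, atlas.class_names, atlas.spacing,
                            atlas.affine.copy())


def prior_responsibility(atlas_priors, gamma, class_of_cluster=None) -> np.ndarray:
    """Mixing-weighted, row-normalized prior cluster weights.

    ``atlas_priors`` is a TissuePriorAtlas (possibly already warped) or a
    raw (..., C) array of class priors; returns an (I, K) matrix over all
    voxels with  w_ik = gamma_k P_i,class(k) / sum_j gamma_j P_i,class(j).
    Voxels where every numerator vanishes fall back to uniform weights.
    """
    P = atlas_priors.priors if isinstance(atlas_priors, TissuePriorAtlas) \
        else np.asarray(atlas_priors, float)
    gamma = np.asarray(gamma, float)
    K = gamma.size
    if class_of_cluster is None:
        class_of_cluster = np.arange(K)
    class_of_cluster = np.asarray(class_of_cluster, int)
    Pc = P.reshape(-1, P.shape[-1])[:, class_of_cluster]
    num = Pc * gamma
    denom = num.sum(axis=1, keepdims=True)
    zero = denom[:, 0] <= 0
    denom[zero] = 1.0
    w = num / denom
    if zero.any():
        log.warning("prior_responsibility: %d voxel(s) with zero prior mass; "
                    "using uniform weights", int(zero.sum()))
        w[zero] = 1.0 / K
    return w


def deformation_penalty(params: DeformationParams, reg: RegularizationConfig
                        ) -> float:
    """Negative log of the Gaussian coefficient prior (constants dropped):
    0.5 * sum_d alpha_d^T C_alpha^-1 alpha_d.  Zero iff alpha == 0."""
    if params.freqs != reg.basis_freqs:
        raise PriorError("alpha dimensions do not match regularization config")
    return float(0.5 * np.sum(params.alpha ** 2 / reg.c_alpha))


def total_deformation_penalty(params: DeformationParams,
                              reg: RegularizationConfig) -> float:
    """Coefficient penalty plus the Gaussian prior on the linear scaling
    (keeps the fitted scaling near unity)."""
    return deformation_penalty(params, reg) + float(
        0.5 * np.sum(((params.scale - 1.0) / reg.scale_prior_sd) ** 2))


def apply_inhomogeneity(y, z_mm, inhomog: float, z_half_extent: float = None):
    """Apply a linear axial intensity gain:  y * (1 + g * z~).

    ``z_mm`` are positions along the scanner (slice) axis relative to the
    volume centre; z~ = z / z_half_extent is the normalized coordinate so
    the coefficient is dimensionless.  ``inhomog = 0`` is the identity.
    """
    y = np.asarray(y, float)
    z = np.asarray(z_mm, float)
    if z_half_extent is None:
        z_half_extent = max(float(np.max(np.abs(z))), 1.0)
    gain = 1.0 + inhomog * z / z_half_extent
    return y * gain


def correct_inhomogeneity(y, z_mm, inhomog: float, z_half_extent: float = None):
    """Invert :func:`apply_inhomogeneity` (divide by the gain, clamped)."""
    y = np.asarray(y, float)
    z = np.asarray(z_mm, float)
    if z_half_extent is None:
        z_half_extent = max(float(np.max(np.abs(z))), 1.0)
    gain = 1.0 + inhomog * z / z_half_extent
    gain = np.where(np.abs(gain) < 0.1, np.sign(gain) * 0.1 + (gain == 0) * 0.1, gain)
    return y / gain


def atlas_to_volume_list(atlas: TissuePriorAtlas) -> list:
    """Split an atlas into per-class probability ImageVolumes (for I/O)."""
    return [ImageVolume(atlas.priors[..., c], atlas.spacing, atlas.affine.copy(),
                        "probability") for c in range(atlas.n_classes)]


def atlas_from_volumes(vols, class_names) -> TissuePriorAtlas:
    ref = vols[0]
    for v in vols[1:]:
        if v.shape != ref.shape:
            raise VolumeError("atlas class maps must share one grid")
    data = np.stack([np.asarray(v.data, float) for v in vols], axis=3)
    return TissuePriorAtlas(np.clip(data, 0, 1), tuple(class_names),
                            ref.spacing, ref.affine.copy())
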