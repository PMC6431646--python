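"""Deformable spatial priors: sine basis, warping, regularization."""

import numpy as np
import pytest
from scipy.interpolate import RegularGridInterpolator
from scipy.optimize import minimize_scalar

import ctbrainseg as cb
from ctbrainseg.priors import PriorError, centered_coords_mm


def uniform_atlas(shape, K):
    data = np.full(shape + (K,), 1.0 / K)
    return cb.TissuePriorAtlas(data, tuple(f"c{i}" for i in range(K)))


# ---------------------------------------------------------------------------
# prior responsibilities
# ---------------------------------------------------------------------------

def test_prior_responsibility_symmetry_annihilation_and_hand_case():
    K = 3
    w = cb.prior_responsibility(uniform_atlas((4, 4, 4), K), np.full(K, 1 / K))
    np.testing.assert_allclose(w, 1.0 / K)

    P = np.zeros((1, 1, 1, 2)); P[..., 0] = 1.0
    w = cb.prior_responsibility(P, [0.5, 0.5])
    np.testing.assert_allclose(w, [[1.0, 0.0]])

    # gamma (0.2, 0.8) with P = (0.5, 0.25): weights (1/3, 2/3)
    P = np.array([0.5, 0.25]).reshape(1, 1, 1, 2)
    w = cb.prior_responsibility(P, [0.2, 0.8])
    np.testing.assert_allclose(w, [[1 / 3, 2 / 3]], rtol=1e-12)


def test_prior_responsibility_rows_normalized_and_zero_row_fallback():
    rng = np.random.default_rng(0)
    P = rng.uniform(0, 1, (5, 5, 5, 3))
    P[0, 0, 0] = 0.0
    w = cb.prior_responsibility(P, [0.2, 0.3, 0.5])
    np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-9)
    np.testing.assert_allclose(w[0], 1 / 3)


# ---------------------------------------------------------------------------
# sine basis
# ---------------------------------------------------------------------------

def test_sine_basis_lowest_mode_and_boundary_zeros():
    b = cb.sine_basis((9, 9, 9), (1, 1, 1))
    col = b.matrix()[:, 0].reshape(9, 9, 9)
    i = np.arange(9)
    expect = np.einsum("x,y,z->xyz", np.sin(np.pi * i / 8),
                       np.sin(np.pi * i / 8), np.sin(np.pi * i / 8))
    np.testing.assert_allclose(col, expect, atol=1e-12)
    assert np.all(col[0] == 0) and np.all(col[-1] == 0)
    assert np.all(col[:, 0] == 0) and np.all(col[:, :, -1] == 0)


def test_sine_basis_columns_orthogonal():
    b = cb.sine_basis((12, 10, 8), (4, 3, 2))
    M = b.matrix()
    gram = M.T @ M
    off = gram - np.diag(np.diag(gram))
    assert np.abs(off).max() <= 1e-8 * np.abs(np.diag(gram)).max()


def test_sine_basis_mode_count_and_bounds():
    assert cb.sine_basis((16, 16, 16), (2, 2, 2)).n_modes == 8
    with pytest.raises(PriorError):
        cb.sine_basis((8, 8, 8), (7, 1, 1))


def test_separable_field_matches_dense_matrix():
    rng = np.random.default_rng(1)
    b = cb.sine_basis((10, 9, 8), (3, 2, 4))
    alpha = rng.normal(size=b.freqs)
    dense = (b.matrix() @ alpha.ravel()).reshape(b.grid_shape)
    np.testing.assert_allclose(b.field(alpha), dense, atol=1e-10)
    v = rng.normal(size=b.grid_shape)
    np.testing.assert_allclose(b.contract(v).ravel(), b.matrix().T @ v.ravel(),
                               atol=1e-10)


# ---------------------------------------------------------------------------
# displacement field
# ---------------------------------------------------------------------------

def test_displacement_zero_alpha_unit_scale_is_zero_field():
    b = cb.sine_basis((8, 8, 8), (2, 2, 2))
    dp = cb.DeformationParams.zero((2, 2, 2))
    fld = cb.displacement_field(dp, b, ((8, 8, 8), (1.0, 1.0, 1.0)))
    assert np.all(fld == 0)


def test_displacement_pure_scaling_is_linear_in_centered_mm():
    shape, spacing = (9, 9, 9), (2.0, 1.0, 1.0)
    b = cb.sine_basis(shape, (2, 2, 2))
    dp = cb.DeformationParams(np.zeros((3, 2, 2, 2)), scale=(1.1, 1.0, 1.0))
    fld = cb.displacement_field(dp, b, (shape, spacing))
    x_mm = centered_coords_mm(shape, spacing)[0]
    np.testing.assert_allclose(fld[0], 0.1 * x_mm, atol=1e-12)
    assert np.all(fld[1] == 0) and np.all(fld[2] == 0)


def test_displacement_single_mode_closed_form():
    shape, spacing = (11, 11, 11), (1.0, 1.0, 1.0)
    b = cb.sine_basis(shape, (1, 1, 1))
    alpha = np.zeros((3, 1, 1, 1)); alpha[1, 0, 0, 0] = 2.5
    fld = cb.displacement_field(cb.DeformationParams(alpha), b, (shape, spacing))
    i = np.arange(11)
    s = np.sin(np.pi * i / 10)
    np.testing.assert_allclose(fld[1], 2.5 * np.einsum("x,y,z->xyz", s, s, s),
                               atol=1e-12)
    assert np.all(fld[0] == 0)


# ---------------------------------------------------------------------------
# warping
# ---------------------------------------------------------------------------

def test_warp_zero_field_identity():
    rng = np.random.default_rng(2)
    P = rng.dirichlet(np.ones(3), size=(6, 6, 6))
    atlas = cb.TissuePriorAtlas(P, ("a", "b", "c"))
    out = cb.warp_priors(atlas, np.zeros((3, 6, 6, 6)))
    np.testing.assert_allclose(out.priors, atlas.priors, atol=1e-12)


def test_warp_integer_shift_moves_one_hot_pattern():
    P = np.zeros((8, 8, 8, 2)); P[..., 1] = 1.0
    P[4, 4, 4] = (1.0, 0.0)
    atlas = cb.TissuePriorAtlas(P, ("fg", "bg"), spacing=(2.0, 1.0, 1.0))
    fld = np.zeros((3, 8, 8, 8)); fld[0] = 2.0  # +1 voxel along x (2 mm)
    out = cb.warp_priors(atlas, fld)
    # backward map: warped(i) = atlas(i + 1), so the spike lands at x=3
    assert out.priors[3, 4, 4, 0] == pytest.approx(1.0)
    assert out.priors[4, 4, 4, 0] == pytest.approx(0.0)


def test_warp_matches_independent_interpolation_oracle():
    rng = np.random.default_rng(3)
    shape, spacing = (10, 9, 8), (1.5, 1.5, 1.25)
    P = rng.dirichlet(np.ones(3), size=shape)
    atlas = cb.TissuePriorAtlas(P, ("a", "b", "c"), spacing=spacing)
    b = cb.sine_basis(shape, (2, 2, 2))
    dp = cb.DeformationParams(rng.normal(0, 0.4, (3, 2, 2, 2)))
    fld = cb.displacement_field(dp, b, (shape, spacing))
    out = cb.warp_priors(atlas, fld)
    grids = [np.arange(n, dtype=float) for n in shape]
    idx = np.indices(shape, dtype=float)
    pts = np.stack([idx[d] + fld[d] / spacing[d] for d in range(3)], axis=-1)
    pts = np.clip(pts, 0, np.asarray(shape, float) - 1)  # boundary value
    for c in range(3):
        itp = RegularGridInterpolator(grids, P[..., c])
        np.testing.assert_allclose(out.priors[..., c],
                                   itp(pts.reshape(-1, 3)).reshape(shape),
                                   atol=1e-9)


def test_warp_conserves_class_mass_for_small_smooth_fields():
    rng = np.random.default_rng(4)
    shape = (16, 16, 16)
    P = rng.dirichlet(np.ones(3) * 5, size=shape)
    from scipy.ndimage import gaussian_filter
    for c in range(3):
        P[..., c] = gaussian_filter(P[..., c], 2.0)
    P /= P.sum(axis=3, keepdims=True)
    atlas = cb.TissuePriorAtlas(P, ("a", "b", "c"))
    b = cb.sine_basis(shape, (1, 1, 1))
    alpha = np.full((3, 1, 1, 1), 0.5)   # sub-voxel amplitude
    fld = cb.displacement_field(cb.DeformationParams(alpha), b, (shape, (1, 1, 1)))
    out = cb.warp_priors(atlas, fld)
    for c in range(3):
        m0, m1 = atlas.priors[..., c].sum(), out.priors[..., c].sum()
        assert abs(m1 - m0) / m0 < 0.02


# ---------------------------------------------------------------------------
# regularization
# ---------------------------------------------------------------------------

def test_penalty_closed_forms_and_scaling():
    reg = cb.RegularizationConfig(basis_freqs=(2, 2, 2))
    z = cb.DeformationParams.zero((2, 2, 2))
    assert cb.deformation_penalty(z, reg) == 0.0
    rng = np.random.default_rng(5)
    a = cb.DeformationParams(rng.normal(size=(3, 2, 2, 2)))
    p1 = cb.deformation_penalty(a, reg)
    p2 = cb.deformation_penalty(cb.DeformationParams(2 * a.alpha), reg)
    assert p2 == pytest.approx(4 * p1, rel=1e-12)
    # single coefficient, diagonal covariance c: penalty a^2 / (2c)
    c = float(reg.c_alpha[1, 0, 1])
    alpha = np.zeros((3, 2, 2, 2)); alpha[2, 1, 0, 1] = 3.0
    assert cb.deformation_penalty(cb.DeformationParams(alpha), reg) == \
        pytest.approx(9.0 / (2 * c), rel=1e-12)


def test_penalty_convex_in_alpha():
    reg = cb.RegularizationConfig(basis_freqs=(2, 2, 2))
    rng = np.random.default_rng(6)
    for _ in range(20):
        a = cb.DeformationParams(rng.normal(size=(3, 2, 2, 2)))
        b = cb.DeformationParams(rng.normal(size=(3, 2, 2, 2)))
        mid = cb.DeformationParams(0.5 * (a.alpha + b.alpha))
        assert cb.deformation_penalty(mid, reg) <= \
            0.5 * (cb.deformation_penalty(a, reg)
                   + cb.deformation_penalty(b, reg)) + 1e-12


# ---------------------------------------------------------------------------
# intensity inhomogeneity
# ---------------------------------------------------------------------------

def test_inhomogeneity_identity_and_axial_slope():
    z = np.linspace(-40, 40, 81)
    y = np.full(81, 30.0)
    np.testing.assert_array_equal(cb.apply_inhomogeneity(y, z, 0.0), y)
    out = cb.apply_inhomogeneity(y, z, 0.05)
    slope = np.polyfit(z, out, 1)[0]
    assert slope == pytest.approx(30.0 * 0.05 / 40.0, rel=1e-9)


def test_inhomogeneity_recovery_flattens_axial_trend():
    rng = np.random.default_rng(7)
    z = np.linspace(-50, 50, 2001)
    base = rng.normal(35.0, 2.0, z.size)
    observed = cb.apply_inhomogeneity(base, z, 0.08)

    def resid_var(g):
        return float(np.var(cb.correct_inhomogeneity(observed, z, g)))

    ghat = minimize_scalar(resid_var, bounds=(-0.2, 0.2), method="bounded").x
    corrected = cb.correct_inhomogeneity(observed, z, ghat)
    slope = np.polyfit(z, corrected, 1)[0]
    assert abs(slope) < 1e-3   # HU per mm
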