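"""Outer estimation loop: EM for the intensity mixture interleaved with
damped Gauss-Newton updates of the deformable spatial priors.

The objective minimized is the regularized mixture cost

    C(theta) = -sum_i log sum_k w_ik(gamma, alpha) N(y_i; mu_k, s2_k)
               + 0.5 sum_d alpha_d^T C_alpha^-1 alpha_d

over within-mask voxels, with w the mixing-weighted warped atlas priors.
Exactly one parameter group is updated at a time (mixture moments, then
deformation, then the axial inhomogeneity gain); every sub-update is
accepted only if the total cost does not increase, so the per-iteration
cost trace is monotone non-increasing by construction.

Initialization: deformation coefficients start at zero; mixture
parameters start from atlas-prior-weighted moment estimates with a small
seeded jitter (a reproducible, better-conditioned stand-in for random
assignment).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage
from scipy.optimize import minimize_scalar

from . import mixture as mx
from .mixture import MixtureParams
from .priors import (DeformationParams, RegularizationConfig, SineBasis,
                     TissuePriorAtlas, apply_inhomogeneity, centered_coords_mm,
                     deformation_penalty, displacement_field, prior_responsibility,
                     total_deformation_penalty, warp_priors)
from .topology import RefineConfig, boundary_refine
from .volumes import (BrainMask, ImageVolume, LabelMap, PosteriorMap,
                      VolumeError, hard_labels, resample_to_grid)

log = logging.getLogger(__name__)

COST_TOL = 1e-8  # absolute slack on "does not increase"


class FitError(RuntimeError):
    pass


@dataclass
class FitConfig:
    """Stopping rules and schedule of the alternating optimization."""

    k_per_class: int = 1
    max_em_iters: int = 64
    em_tol: float = 1e-5            # relative cost-change tolerance
    gn_max_iters: int = 8           # damping doublings per deformation step
    gn_step_damping: float = 0.1    # initial Levenberg damping
    seed: int = 0
    refine_topology: bool = True
    burn_in: int = 3                # mixture-only iterations before deforming
    basis_freqs: tuple = (7, 3, 8)
    c_base: float = 0.5
    fit_inhomogeneity: bool = True
    fit_scale: bool = True
    refine: RefineConfig = dc_field(default_factory=lambda: None)

    def __post_init__(self):
        if self.max_em_iters < 1 or self.gn_max_iters < 1:
            raise FitError("iteration counts must be >= 1")
        if self.em_tol <= 0:
            raise FitError("em_tol must be > 0")
        self.basis_freqs = tuple(int(n) for n in self.basis_freqs)
        if self.refine is None:
            self.refine = RefineConfig()


@dataclass
class SegmentationResult:
    posterior: PosteriorMap
    labels: LabelMap
    mixture: MixtureParams
    deformation: DeformationParams
    cost_trace: list
    converged: bool


# ---------------------------------------------------------------------------
# EM mixture update
# ---------------------------------------------------------------------------

def em_update_mixture(y, resp, current: MixtureParams,
                      variance_floor: float = mx.VARIANCE_FLOOR) -> MixtureParams:
    """Closed-form weighted M-step for the Gaussian mixture.

    mu_k and sigma2_k are responsibility-weighted moments (variance
    floored); gamma_k is the mean responsibility.  Clusters whose total
    responsibility collapses are re-seeded at the global mean with
    inflated variance.
    """
    y = np.asarray(y, float).ravel()
    resp = np.asarray(resp, float)
    n_k = resp.sum(axis=0)
    mu = np.empty_like(current.mu)
    s2 = np.empty_like(current.sigma2)
    empty = n_k < 1e-12
    if empty.any():
        log.warning("em_update_mixture: re-seeding %d empty cluster(s)",
                    int(empty.sum()))
    for k in range(current.n_clusters):
        if empty[k]:
            mu[k] = float(y.mean())
            s2[k] = max(float(y.var()) * 4.0, variance_floor)
        else:
            mu[k] = float(resp[:, k] @ y / n_k[k])
            s2[k] = max(float(resp[:, k] @ (y - mu[k]) ** 2 / n_k[k]),
                        variance_floor)
    gamma = n_k / y.size
    gamma = np.maximum(gamma, 1e-12)
    gamma = gamma / gamma.sum()
    return MixtureParams(mu, s2, gamma, current.class_of_cluster.copy())


# ---------------------------------------------------------------------------
# Damped (Levenberg-regularized) Gauss-Newton step
# ---------------------------------------------------------------------------

def gn_step(cost_fn, grad, hess, x0, damping: float = 0.0,
            max_doublings: int = 8):
    """One damped Gauss-Newton step on a generic objective.

    Solves (H + lam diag(H) + eps I) dx = g and accepts x0 - dx only if
    the cost decreases, doubling ``lam`` otherwise (up to
    ``max_doublings`` attempts).  With ``damping = 0`` and an exactly
    quadratic objective a single step lands at the minimum.

    Returns (x_new, cost_new, accepted).
    """
    g = np.asarray(grad, float)
    H = np.asarray(hess, float)
    c0 = cost_fn(x0)
    lam = damping
    dH = np.diag(H).copy()
    dH[dH <= 0] = 1.0
    for _ in range(max_doublings):
        A = H + lam * np.diag(dH) + 1e-12 * np.eye(H.shape[0])
        try:
            dx = np.linalg.solve(A, g)
        except np.linalg.LinAlgError:
            lam = max(2.0 * lam, 1e-4)
            continue
        x1 = x0 - dx
        c1 = cost_fn(x1)
        if np.isfinite(c1) and c1 <= c0 + COST_TOL:
            return x1, c1, True
        lam = max(2.0 * lam, 1e-4)
    return x0, c0, False


class _DeformationProblem:
    """Caches everything needed to evaluate and differentiate the cost as
    a function of the deformation parameters, at fixed mixture params."""

    def __init__(self, y_corr, mix: MixtureParams, atlas: TissuePriorAtlas,
                 basis: SineBasis, reg: RegularizationConfig, mask: np.ndarray,
                 fit_scale: bool = True):
        self.y = np.asarray(y_corr, float)
        self.mix = mix
        self.atlas = atlas
        self.basis = basis
        self.reg = reg
        self.mask = mask
        self.fit_scale = fit_scale
        self.shape = atlas.grid_shape
        self.coords = centered_coords_mm(self.shape, atlas.spacing)
        sp = atlas.spacing
        self.grads = [
            [np.gradient(atlas.priors[..., c], sp[d], axis=d)
             for d in range(3)]
            for c in range(atlas.n_classes)
        ]
        # per-cluster quantities at fixed mixture params
        self.L = np.exp(mx._log_likelihoods(self.y, mix))        # (I_mask, K)
        cls = mix.class_of_cluster
        C = atlas.n_classes
        self.A = np.zeros((self.y.size, C))                      # sum_k in c g_k L_ik
        self.G = np.zeros(C)
        for k in range(mix.n_clusters):
            self.A[:, cls[k]] += mix.gamma[k] * self.L[:, k]
            self.G[cls[k]] += mix.gamma[k]

    # -- parameter vector packing ------------------------------------------
    def pack(self, dp: DeformationParams) -> np.ndarray:
        v = [dp.alpha.ravel()]
        if self.fit_scale:
            v.append(dp.scale - 1.0)
        return np.concatenate(v)

    def unpack(self, x: np.ndarray, template: DeformationParams
               ) -> DeformationParams:
        M = 3 * self.basis.n_modes
        alpha = x[:M].reshape((3,) + self.basis.freqs)
        scale = 1.0 + x[M:M + 3] if self.fit_scale else template.scale.copy()
        return DeformationParams(alpha, scale, template.inhomog)

    # -- cost and derivatives ----------------------------------------------
    def warped(self, dp: DeformationParams):
        fld = displacement_field(dp, self.basis, (self.shape, self.atlas.spacing))
        return warp_priors(self.atlas, fld), fld

    def cost_parts(self, dp: DeformationParams):
        watlas, _ = self.warped(dp)
        P = watlas.priors[self.mask]
        a = np.einsum("ic,ic->i", P, self.A)
        b = P @ self.G
        good = (a > 0) & (b > 0)
        E = float(-np.sum(np.log(a[good]) - np.log(b[good])))
        E += float(np.sum(~good)) * 50.0  # degenerate voxels: large fixed cost
        return E + total_deformation_penalty(dp, self.reg)

    def cost_from_x(self, x, template):
        return self.cost_parts(self.unpack(x, template))

    def grad_hess(self, dp: DeformationParams):
        watlas, fld = self.warped(dp)
        Pm = watlas.priors[self.mask]
        a = np.einsum("ic,ic->i", Pm, self.A)
        b = Pm @ self.G
        a = np.maximum(a, 1e-300)
        b = np.maximum(b, 1e-300)
        # dE/dP_ic at mask voxels
        dEdP = -self.A / a[:, None] + self.G[None, :] / b[:, None]
        # spatial gradients of warped priors = atlas gradients at x+u
        idx = np.indices(self.shape, dtype=float)
        sp = np.asarray(self.atlas.spacing)
        coords = idx + fld / sp[:, None, None, None]
        V = np.zeros((3,) + self.shape)  # per-axis residual-gradient field
        for c in range(self.atlas.n_classes):
            for d in range(3):
                Dg = ndimage.map_coordinates(self.grads[c][d], coords,
                                             order=1, mode="nearest")
                V[d][self.mask] += dEdP[:, c] * Dg[self.mask]
        M = self.basis.n_modes
        nscale = 3 if self.fit_scale else 0
        P = 3 * M + nscale
        g = np.zeros(P)
        H = np.zeros((P, P))
        for d in range(3):
            g[d * M:(d + 1) * M] = self.basis.contract(V[d]).ravel()
        for d in range(3):
            for e in range(d, 3):
                blk = self.basis.weighted_gram(V[d] * V[e])
                H[d * M:(d + 1) * M, e * M:(e + 1) * M] = blk
                if e != d:
                    H[e * M:(e + 1) * M, d * M:(d + 1) * M] = blk.T
        if self.fit_scale:
            for d in range(3):
                col_w = V[d] * self.coords[d]
                g[3 * M + d] = float(col_w.sum())
                for e in range(3):
                    H[3 * M + d, e * M:(e + 1) * M] = \
                        self.basis.contract(col_w * V[e]).ravel()
                    H[e * M:(e + 1) * M, 3 * M + d] = H[3 * M + d, e * M:(e + 1) * M]
                for e in range(3):
                    H[3 * M + d, 3 * M + e] = float(
                        (V[d] * self.coords[d] * V[e] * self.coords[e]).sum())
        # Gaussian prior on alpha: adds C^-1 alpha to g and C^-1 to H diag
        cinv = (1.0 / self.reg.c_alpha).ravel()
        for d in range(3):
            sl = slice(d * M, (d + 1) * M)
            g[sl] += dp.alpha[d].ravel() * cinv
            H[sl, sl] += np.diag(cinv)
        if self.fit_scale:
            # Gaussian prior keeps scaling near unity and the step well-posed
            for d in range(3):
                j = 3 * M + d
                g[j] += (dp.scale[d] - 1.0) / self.reg.scale_prior_sd ** 2
                H[j, j] += 1.0 / self.reg.scale_prior_sd ** 2
        return g, H


def gauss_newton_update_deformation(y, mix: MixtureParams,
                                    atlas: TissuePriorAtlas,
                                    dparams: DeformationParams,
                                    reg: RegularizationConfig,
                                    basis: SineBasis,
                                    mask: np.ndarray,
                                    damping: float = 0.1,
                                    max_doublings: int = 8,
                                    fit_scale: bool = True):
    """One damped Gauss-Newton step on the deformation parameters.

    ``y`` holds the (inhomogeneity-corrected) within-mask intensities.
    The Gauss-Newton matrix is the Fisher-style outer product of per-voxel
    cost gradients, assembled through separable sine-basis contractions;
    the step is accepted only if the total cost (data term + coefficient
    penalty) decreases, doubling the damping otherwise.

    Returns (new_params, new_cost, accepted).
    """
    prob = _DeformationProblem(y, mix, atlas, basis, reg, mask, fit_scale)
    g, H = prob.grad_hess(dparams)
    x0 = prob.pack(dparams)
    x1, c1, ok = gn_step(lambda x: prob.cost_from_x(x, dparams), g, H, x0,
                         damping=damping, max_doublings=max_doublings)
    if not ok:
        log.info("gauss_newton_update_deformation: no decreasing step found")
        return dparams, c1, False
    return prob.unpack(x1, dparams), c1, True


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def _init_mixture(y, P_cls, atlas_classes, k_per_class, rng) -> MixtureParams:
    """Atlas-prior-weighted moment estimates with seeded jitter."""
    C = P_cls.shape[1]
    mus, s2s, gammas, cls_of = [], [], [], []
    for c in range(C):
        w = P_cls[:, c]
        tot = w.sum()
        if tot <= 0:
            m, v = float(y.mean()), float(y.var())
        else:
            m = float(w @ y / tot)
            v = max(float(w @ (y - m) ** 2 / tot), mx.VARIANCE_FLOOR)
        base_gamma = max(tot / max(P_cls.sum(), 1e-12), 1e-6)
        for j in range(k_per_class):
            jit = rng.normal(0.0, 0.05 * np.sqrt(v))
            off = (j - (k_per_class - 1) / 2.0) * np.sqrt(v)
            mus.append(m + off + jit)
            s2s.append(v)
            gammas.append(base_gamma / k_per_class)
            cls_of.append(c)
    gam = np.asarray(gammas)
    return MixtureParams(np.asarray(mus), np.asarray(s2s), gam / gam.sum(),
                         np.asarray(cls_of))


def fit_segmentation(ct: ImageVolume, mask: BrainMask, atlas: TissuePriorAtlas,
                     config: FitConfig | None = None) -> SegmentationResult:
    """End-to-end atlas-guided mixture segmentation of a head CT.

    Alternates (E-step responsibilities) -> (M-step mixture moments) ->
    (Gauss-Newton deformation) -> (axial inhomogeneity line search) until
    the relative cost change drops below ``em_tol`` or ``max_em_iters`` is
    reached; optionally applies topology-constrained GM/WM boundary
    refinement to the hard labels.
    """
    config = config or FitConfig()
    if mask.shape != ct.shape:
        raise VolumeError("mask grid does not match CT grid")
    if not mask.mask.any():
        raise VolumeError("cannot segment with an empty brain mask")
    if atlas.grid_shape != ct.shape:
        vols = [resample_to_grid(
            ImageVolume(atlas.priors[..., c], atlas.spacing, atlas.affine,
                        "probability"), ct) for c in range(atlas.n_classes)]
        atlas = TissuePriorAtlas(
            np.clip(np.stack([v.data for v in vols], axis=3), 0, 1),
            atlas.class_names, ct.spacing, ct.affine.copy())

    rng = np.random.default_rng(config.seed)
    m = mask.mask
    y_raw = np.asarray(ct.data, float)[m]
    basis = SineBasis(ct.shape, config.basis_freqs)
    reg = RegularizationConfig(basis_freqs=config.basis_freqs,
                               c_base=config.c_base)
    dparams = DeformationParams.zero(config.basis_freqs)  # alpha starts at 0
    z_c = centered_coords_mm(ct.shape, ct.spacing)[2][m]
    z_half = max(float(np.abs(z_c).max()), 1.0)

    P0 = atlas.priors[m]
    mix = _init_mixture(y_raw, P0, atlas.class_names, config.k_per_class, rng)
    warped = atlas  # alpha = 0

    def corrected(dp):
        from .priors import correct_inhomogeneity
        return correct_inhomogeneity(y_raw, z_c, dp.inhomog, z_half)

    def total_cost(mix_, warped_, dp):
        w = prior_responsibility(warped_.priors[m], mix_.gamma,
                                 mix_.class_of_cluster)
        return (mx.neg_log_likelihood(corrected(dp), mix_, w)
                + total_deformation_penalty(dp, reg))

    cost = total_cost(mix, warped, dparams)
    trace = [cost]
    converged = False
    for it in range(config.max_em_iters):
        y_c = corrected(dparams)
        w = prior_responsibility(warped.priors[m], mix.gamma,
                                 mix.class_of_cluster)
        r = mx.responsibilities(y_c, mix, w)
        cand = em_update_mixture(y_c, r, mix)
        c_cand = total_cost(cand, warped, dparams)
        if c_cand <= cost + COST_TOL:
            mix, cost = cand, c_cand
        else:
            # gamma update is approximate under atlas priors: retry with
            # moments only, keeping the previous mixing coefficients
            cand2 = MixtureParams(cand.mu, cand.sigma2, mix.gamma,
                                  mix.class_of_cluster.copy())
            c_cand2 = total_cost(cand2, warped, dparams)
            if c_cand2 <= cost + COST_TOL:
                mix, cost = cand2, c_cand2

        if it >= config.burn_in:
            new_dp, _, ok = gauss_newton_update_deformation(
                corrected(dparams), mix, atlas, dparams, reg, basis, m,
                damping=config.gn_step_damping,
                max_doublings=config.gn_max_iters,
                fit_scale=config.fit_scale)
            if ok:
                fld = displacement_field(new_dp, basis, (ct.shape, ct.spacing))
                new_warped = warp_priors(atlas, fld)
                c_new = total_cost(mix, new_warped, new_dp)
                if c_new <= cost + COST_TOL:
                    dparams, warped, cost = new_dp, new_warped, c_new

            if config.fit_inhomogeneity:
                w_now = prior_responsibility(warped.priors[m], mix.gamma,
                                             mix.class_of_cluster)

                def g_cost(gval):
                    from .priors import correct_inhomogeneity
                    yc = correct_inhomogeneity(y_raw, z_c, gval, z_half)
                    return mx.neg_log_likelihood(yc, mix, w_now)

                res = minimize_scalar(g_cost, bounds=(-0.25, 0.25),
                                      method="bounded",
                                      options={"xatol": 1e-4})
                cand_dp = dparams.copy()
                cand_dp.inhomog = float(res.x)
                c_g = total_cost(mix, warped, cand_dp)
                if c_g <= cost + COST_TOL:
                    dparams, cost = cand_dp, c_g

        trace.append(cost)
        rel = abs(trace[-2] - trace[-1]) / max(abs(trace[-2]), 1.0)
        if rel < config.em_tol:
            converged = True
            break
    if not converged:
        log.warning("fit_segmentation: not converged after %d iterations",
                    config.max_em_iters)

    # posterior over tissue classes
    y_c = corrected(dparams)
    w = prior_responsibility(warped.priors[m], mix.gamma, mix.class_of_cluster)
    r = mx.responsibilities(y_c, mix, w)
    tissue = [c for c in ("wm", "gm", "csf") if c in atlas.class_names]
    probs = np.zeros(ct.shape + (len(tissue),))
    flat = np.zeros((y_raw.size, len(tissue)))
    for k in range(mix.n_clusters):
        name = atlas.class_names[mix.class_of_cluster[k]]
        if name in tissue:
            flat[:, tissue.index(name)] += r[:, k]
    rs = flat.sum(axis=1, keepdims=True)
    rs[rs <= 0] = 1.0
    flat /= rs
    for j in range(len(tissue)):
        probs[..., j][m] = flat[:, j]
    posterior = PosteriorMap(np.clip(probs, 0, 1), tuple(tissue),
                             ct.spacing, ct.affine.copy())
    labels = hard_labels(posterior, mask)
    if config.refine_topology:
        labels = boundary_refine(ct, posterior, labels, config.refine)
    return SegmentationResult(posterior, labels, mix, dparams, trace, converged)
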