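"""Topology-constrained refinement of the GM/WM boundary.

The cortical GM/WM interface is smooth with finite curvature everywhere,
so locally it is well approximated by a plane.  Near the boundary the
probabilistic classification is therefore corrected by a boundary-local,
plane-based decision rule.  For each boundary voxel whose classification
is ambiguous or whose neighbourhood is label-heterogeneous, the plane
through the voxel with minimal intensity variance is selected among a
fixed set of candidate orientations; the voxel's label is then
tentatively flipped between WM and GM, and the flip is kept only if it
decisively lowers the within-class intensity variance of that plane.
Only the flipped voxel changes group, so the variance change reduces to
n/(n+1) (y - mean_L)^2 for joining the label-L plane voxels; requiring
the flipped-label term to be below ``flip_ratio`` times the current-label
term guards the decision against voxel noise.  A correctly labelled
voxel sits in a plane of like-labelled, like-intensity voxels; a
mislabelled one does not.  Only WM and GM labels ever change; CSF and
background are never modified, and voxels farther than the neighbourhood
radius from the WM/GM boundary are untouched.

Candidate plane orientations are the 13 crystallographic neighbour
directions (3 axis, 6 face-diagonal, 4 body-diagonal normals); planes are
defined in voxel space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .volumes import GM, WM, LabelMap, PosteriorMap, VolumeError

log = logging.getLogger(__name__)

_NORMALS = np.array([
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, -1, 1), (1, 1, -1), (1, -1, -1),
], dtype=float)
_NORMALS /= np.linalg.norm(_NORMALS, axis=1, keepdims=True)


@dataclass
class RefineConfig:
    neighborhood_radius: int = 2
    plane_orientations: int = 13
    ambiguity_margin: float = 0.2          # top-two posterior gap
    heterogeneity_threshold: float = 0.3   # discordant-neighbour fraction
    max_passes: int = 10
    min_plane_voxels: int = 3
    flip_ratio: float = 0.5  # required fractional variance decrease

    def __post_init__(self):
        if self.neighborhood_radius < 1:
            raise VolumeError("neighborhood_radius must be >= 1")
        if not (0 < self.ambiguity_margin < 1):
            raise VolumeError("ambiguity_margin must be in (0,1)")
        if not (0 < self.heterogeneity_threshold < 1):
            raise VolumeError("heterogeneity_threshold must be in (0,1)")
        if not (1 <= self.plane_orientations <= len(_NORMALS)):
            raise VolumeError(f"plane_orientations must be 1..{len(_NORMALS)}")


class PlaneFit(NamedTuple):
    normal: np.ndarray
    offset: float               # plane equation n . x = offset (voxel units)
    voxels: np.ndarray          # (n, 3) voxel indices intersecting the plane
    variance: float
    orientation_index: int


def _plane_offsets(config: RefineConfig):
    """Per-orientation integer offsets within the Chebyshev neighbourhood
    that lie within half a voxel of the plane through the origin."""
    r = config.neighborhood_radius
    rng = np.arange(-r, r + 1)
    offs = np.array(np.meshgrid(rng, rng, rng, indexing="ij")).reshape(3, -1).T
    out = []
    for n in _NORMALS[:config.plane_orientations]:
        d = np.abs(offs @ n)
        out.append(offs[d < 0.5])
    return out


def _wm_gm_boundary(labels: np.ndarray) -> np.ndarray:
    """WM/GM voxels with at least one 6-neighbour of the other class."""
    is_wm = labels == WM
    is_gm = labels == GM
    bnd = np.zeros(labels.shape, dtype=bool)
    for axis in range(3):
        for shift in (1, -1):
            other = np.roll(labels, shift, axis=axis)
            # roll wraps around; suppress the wrapped face
            edge = [slice(None)] * 3
            edge[axis] = slice(0, 1) if shift == 1 else slice(-1, None)
            valid = np.ones(labels.shape, dtype=bool)
            valid[tuple(edge)] = False
            bnd |= is_wm & (other == GM) & valid
            bnd |= is_gm & (other == WM) & valid
    return bnd


def local_plane_search(ct, labels: LabelMap, voxel, config: RefineConfig
                       ) -> PlaneFit:
    """Minimum-intensity-variance plane through a boundary voxel.

    Among the candidate orientations, returns the plane whose intersected
    neighbourhood voxels (all labels) have minimal intensity variance;
    ties break to the lowest orientation index.  Raises if the voxel has
    no 6-neighbour of the opposite WM/GM class.
    """
    data = np.asarray(ct.data, float)
    lab = labels.labels
    voxel = tuple(int(v) for v in voxel)
    if lab[voxel] not in (WM, GM):
        raise VolumeError("local_plane_search requires a WM or GM voxel")
    if not _wm_gm_boundary(lab)[voxel]:
        raise VolumeError("voxel is not adjacent to the WM/GM boundary")
    best = None
    for oi, offs in enumerate(_plane_offsets(config)):
        pts = np.asarray(voxel) + offs
        ok = np.all((pts >= 0) & (pts < np.asarray(lab.shape)), axis=1)
        pts = pts[ok]
        vals = data[pts[:, 0], pts[:, 1], pts[:, 2]]
        var = float(np.var(vals)) if vals.size else np.inf
        if best is None or var < best[0]:
            best = (var, oi, pts)
    var, oi, pts = best
    n = _NORMALS[oi]
    return PlaneFit(n, float(n @ np.asarray(voxel, float)), pts, var, oi)


def _masked_min_variance(vals, sel, counts_min):
    """Row-wise variance over selected entries; inf when too few."""
    cnt = sel.sum(axis=1)
    safe = np.maximum(cnt, 1)
    s1 = np.where(sel, vals, 0.0).sum(axis=1)
    s2 = np.where(sel, vals * vals, 0.0).sum(axis=1)
    mean = s1 / safe
    var = s2 / safe - mean ** 2
    var = np.maximum(var, 0.0)
    return np.where(cnt >= counts_min, var, np.inf)


def boundary_refine(ct, posterior: PosteriorMap, labels: LabelMap,
                    config: RefineConfig | None = None) -> LabelMap:
    """Plane-variance-guided WM<->GM relabelling near the boundary.

    Sweeps over WM/GM boundary voxels that are ambiguous (top-two
    posterior gap below ``ambiguity_margin``) or label-heterogeneous
    (fraction of differently-labelled 26-neighbours above
    ``heterogeneity_threshold``); a voxel is flipped when joining the
    other label's voxels in the selected (minimum-variance) plane raises
    the within-class in-plane variance by decisively less than staying in
    its own — see the module docstring for the exact rule.  Flips are
    applied simultaneously per pass; passes repeat until no voxel flips
    or ``max_passes`` is reached.
    """
    config = config or RefineConfig()
    data = np.asarray(ct.data, float)
    lab = labels.labels.copy()
    r = config.neighborhood_radius
    pad = r
    dpad = np.pad(data, pad, constant_values=np.nan)
    offsets = _plane_offsets(config)

    # posterior ambiguity: gap between the two largest class posteriors
    p = np.sort(posterior.probs, axis=3)
    gap = p[..., -1] - p[..., -2] if p.shape[3] >= 2 else np.ones(p.shape[:3])

    total_flips = 0
    for _ in range(config.max_passes):
        lpad = np.pad(lab, pad, constant_values=255)
        bnd = _wm_gm_boundary(lab)
        if not bnd.any():
            break
        pos = np.argwhere(bnd)
        # heterogeneity: differently-labelled fraction of the 26-neighbours
        centre_lab = lab[bnd]
        nb = np.array(np.meshgrid([-1, 0, 1], [-1, 0, 1], [-1, 0, 1],
                                  indexing="ij")).reshape(3, -1).T
        nb = nb[np.any(nb != 0, axis=1)]
        npts = pos[:, None, :] + nb[None, :, :] + pad
        nlab = lpad[npts[..., 0], npts[..., 1], npts[..., 2]]
        valid = nlab != 255
        disc = (nlab != centre_lab[:, None]) & valid
        frac = disc.sum(axis=1) / np.maximum(valid.sum(axis=1), 1)
        ambiguous = gap[bnd] < config.ambiguity_margin
        hetero = frac > config.heterogeneity_threshold
        cand = ambiguous | hetero
        if not cand.any():
            break
        pos = pos[cand]
        centre_lab = centre_lab[cand]

        # plane selection: minimal all-voxel intensity variance, ties to the
        # lowest orientation index; the flip is then judged on that plane only
        all_var, cwm, cgm = [], [], []
        centre_val = np.asarray(data[pos[:, 0], pos[:, 1], pos[:, 2]])
        for offs in offsets:
            pts = pos[:, None, :] + offs[None, :, :] + pad
            vals = dpad[pts[..., 0], pts[..., 1], pts[..., 2]]
            labs = lpad[pts[..., 0], pts[..., 1], pts[..., 2]]
            centre_col = np.all(offs == 0, axis=1)
            finite = np.isfinite(vals)
            vals = np.nan_to_num(vals)
            all_var.append(_masked_min_variance(vals, finite, 1))
            # within-class in-plane variance change from adding the centre to
            # class L: n_L/(n_L+1) (y_c - mean_L)^2 over the centre-excluded
            # label-L plane voxels; inf when the class is under-represented
            per_class = {}
            for L in (WM, GM):
                sel = (labs == L) & finite
                sel[:, centre_col] = False
                n = sel.sum(axis=1)
                s = np.where(sel, vals, 0.0).sum(axis=1)
                mean = s / np.maximum(n, 1)
                cost = n / (n + 1.0) * (centre_val - mean) ** 2
                per_class[L] = np.where(n >= config.min_plane_voxels - 1,
                                        cost, np.inf)
            cwm.append(per_class[WM])
            cgm.append(per_class[GM])
        best = np.argmin(np.stack(all_var), axis=0)
        cwm = np.take_along_axis(np.stack(cwm), best[None, :], axis=0)[0]
        cgm = np.take_along_axis(np.stack(cgm), best[None, :], axis=0)[0]

        cur = np.where(centre_lab == WM, cwm, cgm)
        alt = np.where(centre_lab == WM, cgm, cwm)
        # decisive decrease only: guards against chasing voxel noise
        flip = alt < config.flip_ratio * cur
        if not flip.any():
            break
        fp = pos[flip]
        new_lab = np.where(centre_lab[flip] == WM, GM, WM).astype(lab.dtype)
        lab[fp[:, 0], fp[:, 1], fp[:, 2]] = new_lab
        total_flips += int(flip.sum())
    log.info("boundary_refine: %d flip(s) total", total_flips)
    return LabelMap(lab, labels.spacing, labels.affine.copy())
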