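"""Quantitative segmentation comparison suite.

Implements the evaluation measures used to compare a test segmentation
against a co-registered reference label map: the Sørensen-Dice overlap
coefficient, the modified Hausdorff distance between class boundary
surfaces (Dubuisson-Jain variant, in world mm), the one-way
random-effects intraclass correlation of volume measurements, the mean
absolute stretching distance of the prior deformation, a bootstrap
estimate of expected percent volume error, and the contrast-ablation
control comparison with a paired sign-flip permutation test.

Conventions: boundary surfaces are labelled voxels with at least one
differently-labelled 6-neighbour; distances honour anisotropic voxel
spacing; CSF comparisons are restricted to ventricular (interior) CSF;
degenerate Dice cases are both-empty = 1 (logged), one-empty = 0.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .phantom import ablate_contrast
from .volumes import (CSF, GM, WM, BrainMask, ImageVolume, LabelMap,
                      VolumeError, extract_ventricular_csf)

log = logging.getLogger(__name__)

CLASS_CODES = {"wm": WM, "gm": GM, "csf": CSF}


class MetricError(ValueError):
    pass


@dataclass
class EvaluationReport:
    dice_per_class: dict = field(default_factory=dict)       # fraction
    mhd_per_class: dict = field(default_factory=dict)        # mm
    volumes: dict = field(default_factory=dict)              # mm^3, per source
    icc_per_class: dict = field(default_factory=dict)
    stretch_mm: float | None = None
    bootstrap_error: dict = field(default_factory=dict)      # percent + CI

    def to_dict(self) -> dict:
        return {
            "dice_per_class": self.dice_per_class,
            "mhd_per_class": self.mhd_per_class,
            "volumes_mm3": self.volumes,
            "icc_per_class": self.icc_per_class,
            "stretch_mm": self.stretch_mm,
            "bootstrap_error": self.bootstrap_error,
        }


def dice(x: np.ndarray, y: np.ndarray) -> float:
    """Sørensen-Dice coefficient 2|X∩Y| / (|X|+|Y|) of two voxel sets.

    1 for perfect overlap, 0 for none.  Both-empty is defined as 1
    (logged); one-empty is 0.
    """
    x = np.asarray(x, bool)
    y = np.asarray(y, bool)
    if x.shape != y.shape:
        raise MetricError(f"grid mismatch: {x.shape} vs {y.shape}")
    nx, ny = int(x.sum()), int(y.sum())
    if nx + ny == 0:
        log.info("dice: both sets empty; returning 1 by convention")
        return 1.0
    return 2.0 * int((x & y).sum()) / (nx + ny)


def boundary_voxels(mask: np.ndarray) -> np.ndarray:
    """Surface voxels of a class set: members with a 6-neighbour outside."""
    mask = np.asarray(mask, bool)
    er = ndimage.binary_erosion(mask, structure=ndimage.generate_binary_structure(3, 1))
    return mask & ~er


def modified_hausdorff(x: np.ndarray, y: np.ndarray, spacing) -> float:
    """Dubuisson-Jain modified Hausdorff distance between two boundary
    voxel sets, in world mm:  max of the two directed mean
    nearest-neighbour Euclidean distances (anisotropic spacing honoured).

    ``x`` and ``y`` are boolean grids of boundary voxels or (n, 3) index
    arrays.
    """
    sp = np.asarray(spacing, float)

    def pts(a):
        a = np.asarray(a)
        if a.dtype == bool or a.ndim == 3:
            a = np.argwhere(np.asarray(a, bool))
        return np.asarray(a, float) * sp

    px, py = pts(x), pts(y)
    if px.size == 0 or py.size == 0:
        raise MetricError("modified Hausdorff undefined for an empty set")
    dx = cKDTree(py).query(px, k=1)[0]
    dy = cKDTree(px).query(py, k=1)[0]
    return float(max(dx.mean(), dy.mean()))


def icc_oneway(measurements) -> float:
    """One-way random-effects intraclass correlation of paired volumes.

    ``measurements`` is an (n_subjects, n_repeats) array (two repeats for
    a two-method comparison).  MS_between and MS_within are the one-way
    ANOVA mean squares with subject as the grouping factor and the
    statistic is (MS_b - MS_w) / MS_b.
    """
    m = np.asarray(measurements, float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise MetricError("need >= 2 subjects with >= 2 measurements each")
    n, k = m.shape
    grand = m.mean()
    row_means = m.mean(axis=1)
    ss_b = k * np.sum((row_means - grand) ** 2)
    ss_w = np.sum((m - row_means[:, None]) ** 2)
    ms_b = ss_b / (n - 1)
    ms_w = ss_w / (n * (k - 1))
    if ms_b == 0:
        raise MetricError("ICC undefined: between-subject mean square is zero")
    return float((ms_b - ms_w) / ms_b)


def stretching_distance(field_mm: np.ndarray, mask) -> float:
    """Mean absolute stretching distance d_S: the average Euclidean norm
    of the displacement field over within-mask voxels, in mm."""
    fld = np.asarray(field_mm, float)
    m = mask.mask if isinstance(mask, BrainMask) else np.asarray(mask, bool)
    if not m.any():
        raise MetricError("stretching_distance requires a nonempty mask")
    if not np.all(np.isfinite(fld)):
        raise MetricError("displacement field must be finite")
    norms = np.sqrt(np.sum(fld[:, m] ** 2, axis=0))
    return float(norms.mean())


def bootstrap_volume_error(pairs, n_boot: int = 2000, seed: int = 0) -> dict:
    """Expected percent deviation of test volumes from reference volumes.

    ``pairs`` is a sequence of (reference_volume, test_volume) per
    subject.  Per-subject deviation is |V_test - V_ref| / V_ref * 100;
    the mean deviation is bootstrapped over subjects (with replacement,
    seeded) and reported with its mean ± 2·SD confidence interval.
    """
    pairs = [(float(r), float(t)) for r, t in pairs]
    dev = []
    for r, t in pairs:
        if r == 0:
            warnings.warn("bootstrap_volume_error: zero reference volume; "
                          "subject excluded")
            continue
        dev.append(abs(t - r) / r * 100.0)
    if len(dev) < 2:
        raise MetricError("need >= 2 subjects with nonzero reference volumes")
    dev = np.asarray(dev)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, dev.size, size=(n_boot, dev.size))
    boot_means = dev[idx].mean(axis=1)
    mean = float(boot_means.mean())
    sd = float(boot_means.std())
    return {"mean_pct": mean, "ci_low_pct": mean - 2 * sd,
            "ci_high_pct": mean + 2 * sd, "sd_pct": sd}


def evaluate_pair(test: LabelMap, reference: LabelMap,
                  deformation_field: np.ndarray | None = None,
                  mask: np.ndarray | None = None) -> EvaluationReport:
    """Per-class Dice + modified Hausdorff between two co-registered label
    maps, class volumes in mm^3, and (optionally) the stretching distance.

    WM and GM are compared over all intracranial voxels; CSF is first
    restricted to its ventricular (interior) component on both maps.
    Classes absent from the reference are reported as absent (warning).
    """
    if test.shape != reference.shape:
        raise MetricError("label maps must share one grid")
    sp = np.asarray(test.spacing, float)
    voxvol = float(np.prod(sp))
    rep = EvaluationReport()
    test_v = {"wm": test.class_mask(WM), "gm": test.class_mask(GM)}
    ref_v = {"wm": reference.class_mask(WM), "gm": reference.class_mask(GM)}
    test_v["csf"] = extract_ventricular_csf(test, mask).class_mask(CSF)
    ref_v["csf"] = extract_ventricular_csf(reference, mask).class_mask(CSF)
    for name in ("wm", "gm", "csf"):
        t, r = test_v[name], ref_v[name]
        rep.volumes.setdefault("test", {})[name] = float(t.sum()) * voxvol
        rep.volumes.setdefault("reference", {})[name] = float(r.sum()) * voxvol
        if not r.any():
            warnings.warn(f"evaluate_pair: reference has no {name} voxels")
            rep.dice_per_class[name] = None
            rep.mhd_per_class[name] = None
            continue
        rep.dice_per_class[name] = dice(t, r)
        if t.any():
            rep.mhd_per_class[name] = modified_hausdorff(
                boundary_voxels(t), boundary_voxels(r), sp)
        else:
            rep.mhd_per_class[name] = None
    if deformation_field is not None:
        m = mask if mask is not None else (reference.labels != 0)
        rep.stretch_mm = stretching_distance(deformation_field, m)
    return rep


def paired_permutation_test(differences, n_perm: int = 1000, seed: int = 0
                            ) -> float:
    """Two-sided sign-flip permutation p-value for paired differences
    having zero mean."""
    d = np.asarray(differences, float)
    if d.size < 2:
        raise MetricError("need >= 2 paired differences")
    rng = np.random.default_rng(seed)
    obs = abs(d.mean())
    signs = rng.choice([-1.0, 1.0], size=(n_perm, d.size))
    null = np.abs((signs * d).mean(axis=1))
    return float((1 + np.sum(null >= obs - 1e-15)) / (n_perm + 1))


def ablation_comparison(ct: ImageVolume, mask: BrainMask, atlas, config,
                        reference: LabelMap, seed: int = 0) -> dict:
    """Segment the original CT and its contrast-ablated counterpart with
    the same configuration, evaluate both against the reference, and
    report the per-class paired Dice/mHd differences (original - ablated).
    """
    from .fit import fit_segmentation

    res_orig = fit_segmentation(ct, mask, atlas, config)
    ct_abl = ablate_contrast(ct, mask, seed)
    res_abl = fit_segmentation(ct_abl, mask, atlas, config)
    rep_orig = evaluate_pair(res_orig.labels, reference, mask=mask.mask)
    rep_abl = evaluate_pair(res_abl.labels, reference, mask=mask.mask)
    diffs = {}
    for name in ("wm", "gm"):
        a, b = rep_orig.dice_per_class[name], rep_abl.dice_per_class[name]
        diffs[f"dice_{name}"] = None if a is None or b is None else a - b
        a, b = rep_orig.mhd_per_class[name], rep_abl.mhd_per_class[name]
        diffs[f"mhd_{name}"] = None if a is None or b is None else a - b
    return {"original": rep_orig, "ablated": rep_abl, "differences": diffs}
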