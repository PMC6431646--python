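"""Shared fixtures: small phantoms and cached segmentation cohorts.

Expensive end-to-end segmentations are computed once per session and
shared between the tests that consume them.
"""

import numpy as np
import pytest

import ctbrainseg as cb


def small_phantom_spec(seed=0, **kw):
    """A compact phantom that still contains every compartment."""
    defaults = dict(grid_shape=(32, 32, 32), spacing=(2.5, 2.5, 2.5),
                    ventricle_radius_mm=5.0, seed=seed)
    defaults.update(kw)
    return cb.PhantomSpec(**defaults)


@pytest.fixture(scope="session")
def small_phantom():
    return cb.make_head_phantom(small_phantom_spec(seed=7))


@pytest.fixture(scope="session")
def default_phantom():
    """The default-condition 64^3 phantom used by end-to-end checks."""
    return cb.make_head_phantom(cb.PhantomSpec(seed=42))


@pytest.fixture(scope="session")
def default_segmentation(default_phantom):
    """Full-pipeline segmentation of the default phantom with a blurred,
    misaligned atlas (refinement applied separately by consumers)."""
    res = default_phantom
    atlas = cb.make_synthetic_atlas(res)
    cfg = cb.FitConfig(max_em_iters=25, seed=42, refine_topology=False)
    return cb.fit_segmentation(res.ct, res.mask, atlas, cfg)


COHORT_SEEDS = tuple(range(1, 11))


@pytest.fixture(scope="session")
def phantom_cohort():
    """Ten 48^3 phantom subjects segmented with and without contrast
    ablation; drives the ablation and refinement cohort properties."""
    subjects = []
    for seed in COHORT_SEEDS:
        spec = cb.make_cohort_spec(seed)
        res = cb.make_head_phantom(spec)
        atlas = cb.make_synthetic_atlas(res)
        cfg = cb.FitConfig(max_em_iters=12, seed=seed, refine_topology=False)
        fit = cb.fit_segmentation(res.ct, res.mask, atlas, cfg)
        abl = cb.ablate_contrast(res.ct, res.mask, seed)
        fit_abl = cb.fit_segmentation(abl, res.mask, atlas, cfg)
        subjects.append({"phantom": res, "fit": fit, "fit_ablated": fit_abl})
    return subjects
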