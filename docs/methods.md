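# Methods

This note documents the model, the numerical choices, the synthetic
data the tests run on, and what those tests do and do not establish.

## Generative model

Within a brain mask of `I` voxels, CT intensities `y_i` (Hounsfield
units) are modelled as draws from a mixture of `K` Gaussian clusters
(`μ_k`, `σ_k²`, mixing coefficient `γ_k`, `Σγ_k = 1`).  Each cluster is
assigned to one tissue class; the default is one cluster per atlas class
(WM, GM, CSF, plus a background class when the atlas carries one, giving
K = 4).  `k_per_class > 1` splits each class into several clusters for
heavier-tailed intensity distributions.

A tissue-prior atlas supplies per-voxel class probabilities `P_ik`.  The
cluster prior at voxel `i` is the mixing-weighted, row-normalized
`γ_k P_ik(α) / Σ_j γ_j P_ij(α)`, where `α` parameterizes a smooth
deformation of the atlas: per axis, a linear combination of the lowest
discrete-sine modes (separable products `sin(πm₁x̃)sin(πm₂ỹ)sin(πm₃z̃)`
on normalized grid coordinates; every mode vanishes on the grid faces
and the modes are orthogonal on the grid), plus one linear scaling
parameter per axis acting about the grid centre.  One further scalar
models a multiplicative, linear-in-slice-position intensity gain (the
correction divides observed intensities by `1 + g·z̃` with `z̃` the
centred, half-extent-normalized slice coordinate; whether such a gain
should multiply or add is not determined by the data we target, and the
multiplicative form was chosen).  Warping is backward (atlas values are
pulled to subject space), so every subject voxel has a defined prior;
out-of-grid samples take the atlas boundary value.

The fitted objective is the negative log-likelihood of the mixture under
these priors plus Gaussian penalties: `½ Σ_d α_dᵀ C_α⁻¹ α_d` on the sine
coefficients and `½ Σ_d ((s_d − 1)/0.05)²` on the scaling.  `C_α` is
diagonal with variance `c_base · 9/(m₁²+m₂²+m₃²)²` — a bending-energy
style decay that penalizes high-frequency modes most.

## Parameters that matter

| parameter | default | unit | rationale |
|---|---|---|---|
| `basis_freqs` | (7, 3, 8) | modes/axis | the published frequency triple; configurable (never hard-coded as a total of 392, which is inconsistent with 7·3·8 = 168) |
| `c_base` | 0.5 | mm² | prior SD ≈ 0.7 mm on the lowest mode; chosen by parameter-recovery study (see Limitations) — weaker priors let boundary-sharpening warps dominate |
| `scale_prior_sd` | 0.05 | — | scaling is weakly identified against low-frequency sine modes inside the mask; the prior keeps it near unity |
| `k_per_class` | 1 | — | CT offers ~7 HU GM−WM contrast; one Gaussian per class is adequate on phantoms |
| `em_tol` / `max_em_iters` | 1e-5 / 64 | rel. / — | typical convergence in 10–25 iterations |
| `burn_in` | 3 | iterations | mixture moments stabilize before deformation steps begin |
| variance floor | 1e-3 | HU² | prevents cluster collapse |
| brain-mask thresholds | (−200, 100) | HU | excludes air and bone; opening radius 2 voxels, largest component, hole filling; always overridable by a supplied mask |
| refinement `ambiguity_margin` / `heterogeneity_threshold` / `flip_ratio` | 0.2 / 0.3 / 0.5 | — | see below |

## Optimization

Parameters are updated one group at a time: (E-step responsibilities) →
(closed-form M-step for `μ, σ², γ`) → (one damped Gauss-Newton step on
`α` and scale) → (bounded 1-D search on the inhomogeneity gain).  The
`γ` update (mean responsibility) is exact only for spatially constant
priors, so *every* sub-update is accepted only if the total cost does
not increase (tolerance 1e-8); the per-iteration cost trace is therefore
monotone non-increasing by construction, and a rejected step leaves the
previous value in place.  The Gauss-Newton matrix is the Fisher-style
outer product of per-voxel cost gradients, assembled with separable
tensor contractions over the sine factors (never materializing the dense
basis), with the penalty curvature added; steps use Levenberg damping
that doubles until the cost decreases.  Initialization: `α = 0`, unit
scale, zero gain; mixture parameters from atlas-prior-weighted moments
with a small seeded jitter (a reproducible replacement for random
assignment — random starts and the jitter differ only in
conditioning, and the seed makes runs bit-reproducible).

## Topology-constrained refinement

The cortical GM/WM interface is smooth, so near the boundary the correct
label configuration is locally planar.  For each WM/GM boundary voxel
that is ambiguous (top-two posterior gap < 0.2) or label-heterogeneous
(> 30 % discordant 26-neighbours), the plane through the voxel with
minimal all-voxel intensity variance is selected among 13 candidate
orientations (axis, face-diagonal and body-diagonal normals, radius 2,
in voxel space).  The voxel joins whichever label's in-plane group
raises the within-class variance least — the change reduces to
`n/(n+1)·(y − mean_L)²` — and is flipped only when the flipped-label
term is below `flip_ratio = 0.5` of the current-label term.  The
decisiveness ratio exists because a label flip cannot change any
unconditional intensity variance, and an unguarded comparison of two
noisy variance estimates flips ~20 % of boundary voxels on noise alone,
degrading accuracy.  Flips are applied simultaneously per pass; passes
repeat (≤ 10) until none flip.  CSF and background labels are never
modified.  At the phantom's default noise the refinement raises median
per-class Dice slightly (+0.002 over ten seeds); at several times that
noise it begins to undo prior-informed decisions, which is the expected
failure mode of any intensity-only local rule.

## Synthetic phantom

The phantom emulates the *structure* of a head CT, not its physics:
nested compartments (ellipsoidal WM core with low-order sinusoidal,
gyrus-like surface undulation; 5 mm cortical GM shell; paired spherical
6 mm "ventricles"; 2 mm surface CSF film; 3 mm bone shell at 1000 HU;
air at −1000 HU) with Gaussian class intensities — GM 38.7 ± 2.2 HU and
WM 31.8 ± 2.3 HU, the published standard-dose radiodensities; CSF
8 ± 3 HU, a clinically typical value — plus 1 HU of global noise.  Each
phantom carries a known smooth deformation drawn in the sine family
(lowest (3,3,3) modes, amplitude-normalized, default 2 mm peak), and
`make_synthetic_atlas` builds the matching imperfect atlas: one-hot
truth blurred to 4 mm FWHM (a partition of unity over WM/GM/CSF/
background) and warped against the stored deformation, so the fitter
should recover the stored field with positive sign.  Cohorts use
`make_cohort_spec`, which varies brain radii, ventricle size and
cortical thickness per seed so that between-subject volume variance is
realistic (without it the one-way ICC is undefined).

What the phantom does **not** emulate: partial-volume averaging at class
boundaries (labels are crisp and intensities i.i.d. per class), spatially
correlated noise, beam hardening and reconstruction-kernel effects,
pathology, and real anatomical shape variation.  Consequently phantom
Dice values (≈ 0.98) are far above what patient CT-vs-MRI comparisons
yield, and the refinement stage has little systematic error left to
correct; passing tests establish correctness and internal consistency of
the machinery, not clinical accuracy.

## Problem sizes used in tests and the acceptance script

End-to-end checks run on the default 64³ phantom (1.5 × 1.5 × 1.25 mm
voxels); cohort properties (ablation, refinement medians, ICC,
bootstrap) on ten (tests) or eight (script) 48³ subjects at 12 EM
iterations; unit tests on 32³ phantoms at 2.5 mm spacing.  The
down-sampling experiment resamples the 64³ phantom to 3.75 mm slices by
trilinear interpolation (nearest-neighbour for labels) and scores each
resolution against its own-grid truth.  These sizes were chosen as the
smallest grids on which every compartment of the phantom geometry is
resolved.

## Design choices where the design was open

- **Hard labels** are the per-voxel argmax of the class posterior inside
  the mask; ties break by the fixed order WM < GM < CSF.
- **Ventricular CSF** is operationalized as CSF connected components
  (26-connectivity) that do not touch the outermost brain-mask layer.
- **Dice degenerate cases**: both-empty = 1 (logged), one-empty = 0.
- **Boundary surfaces** for the modified Hausdorff distance are labelled
  voxels with at least one differently-labelled 6-neighbour; distances
  are Euclidean in world mm with anisotropic spacing honoured.
- **Paired significance** for the ablation control uses a seeded
  sign-flip permutation test on per-subject differences.
- **Bootstrap volume error**: per-subject |V_test − V_ref|/V_ref · 100,
  resampled over subjects (2000 draws), reported as mean ± 2·SD.
- The cohort ICC uses raw volumes in mm³.

## Known limitations

- **Atlas-blur sharpening bias.**  When the atlas blur is large relative
  to the true misalignment, the maximum-a-posteriori deformation
  acquires a boundary-normal "sharpening" component (compressing the
  blurred prior edge genuinely lowers the cost).  This also makes joint
  scale estimation drift toward ~1.2 on blurred synthetic atlases
  (uniform magnification sharpens the prior edge), which the scale prior
  counteracts.  Deformation-recovery accuracy is therefore assessed on
  interior voxels (mask eroded by 4 voxels), where fitted-vs-truth
  cosine similarity is 0.78–0.89 at 2-voxel misalignment amplitudes;
  over the whole mask, edge contamination lowers it by ≈ 0.03.
  Stronger regularization does not help (it suppresses the true field
  as much as the artefact).
- The deformation is a small-parameter sine expansion: no
  diffeomorphism guarantee and no multi-resolution pyramid; large
  misalignments should be handled by affine pre-registration, which this
  package applies but does not estimate.
- The refinement rule is intensity-only and local; under spatially
  i.i.d. noise it cannot outperform the posterior argmax, and its
  benefit on real data rests on errors being spatially structured.
- The contrast-ablation experiment reproduces the published control
  directionally (WM/GM Dice drop, p from a permutation test); patient
  cohort magnitudes are not reproducible without the original data.
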