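# Methods

This document describes the models and numerical choices behind
`fetalsubseg`: a pipeline for few-shot segmentation of subcortical
structures — choroid plexus (CP), lateral posterior ventricle horn
(LPVH), cavum septi pellucidi et vergae (CSPV) and cerebellum (CB) — in
3D fetal neurosonography, evaluated end to end on a synthetic phantom
cohort.

## 1. Synthetic phantom cohort (`phantom`)

Real fetal ultrasound volumes cannot ship with a package; the phantom
module generates ultrasound-like volumes whose geometry, growth and
artefacts follow the published qualitative behaviour of the fetal brain
between 18 and 26 gestational weeks (GW).

**Geometry.** The brain is an ellipsoid with semi-axis ratios
1.25 : 1 : 0.92 whose volume follows a linear law
V̄_brain(t) = 33 + 9·t cm³ with t = GA − 18 weeks (33 cm³ at 18 GW to
105 cm³ at 26 GW). Each subcortical structure is an ellipsoid placed at
an anatomically plausible relative position; lateralized structures (CP,
LPVH) are placed in the subject's *visible* hemisphere only, mimicking
the acoustic-shadowing constraint that makes the transducer-proximal
hemisphere unusable in real scans.

**Growth laws** (cm³, t = GA − 18):

| structure | law | 18 GW | 26 GW |
|---|---|---|---|
| brain | 33 + 9 t | 33 | 105 |
| CP | 4.0 + 0.0375 t (absolute) | 4.0 | 4.3 |
| LPVH | 0.1 + 0.025 t | 0.10 | 0.30 |
| CSPV | 0.01 + 0.07375 t | 0.01 | 0.60 |
| CB | (0.017 + 0.00075 t) · V̄_brain | 0.56 | 2.41 |

All laws are non-decreasing over [18, 26]. CP relative volume declines
from ≈12% to ≈4% while its absolute volume grows very slightly, matching
the published narrative. Structure *shape* is jittered per subject
(semi-axis ratios and centre), but the scale is recomputed after
jittering, so the analytic volume matches the law exactly; residual
volume noise comes from voxelization and clipping to the brain mask.

**Appearance.** Piecewise-constant tissue intensities, Gaussian
smoothing, a smoothstep attenuation ramp into the occluded hemisphere
(acoustic shadow) and multiplicative gamma speckle whose strength scales
inversely with the configured image `quality`. Each subject also carries
a random rigid `pose` so that aligned/unaligned experiments can be run
from the same cohort.

**Limits of realism.** The phantom is a geometric stand-in: no
convolutional PSF, no refraction, no anatomy beyond five ellipsoidal
compartments, no inter-subject volume variability beyond voxelization.
It is designed so that *relative* statements (e.g. "clustered templates
beat a single template", "alignment helps expert-label models") are
meaningful, not to reproduce absolute published accuracy numbers.

## 2. Groupwise templates and atlas labels (`templates`)

Per gestational week (GA rounded to the nearest integer week,
`week_bin`), a groupwise intensity template is built per hemisphere by
iterated diffeomorphic demons registration (SimpleITK
fast-symmetric-forces demons; displacement fields in voxel units,
pull-back convention). Each iteration registers every member to the
current mean and re-averages; inverse fields are obtained by fixed-point
inversion (tolerance 0.1 voxel in the interior).

Template labels are produced by warping member ground-truth labels into
template space and majority voting (the published pipeline annotates
templates manually; the phantom pipeline has no human in the loop).
Left/right hemisphere templates are fused by mirroring across the
midsagittal plane; a missing hemisphere is filled with the mirrored
opposite template. "Weak" atlas annotations for any subject are obtained
by propagating the fused template labels through the subject's inverse
deformation field; lateralized structures are restricted to the
subject's visible hemisphere.

## 3. Cluster-based LPVH templates (`cluster`)

The LPVH varies too much in shape for a single weekly template. Within a
GA window, LPVH-centred crops are compared by masked sum of squared
differences after demons alignment, giving a pairwise distance matrix.
Outliers (mean distance > n_sigma above the cohort mean; default 2σ) are
held out, the rest are clustered by k-medoids (PAM) with a minimum
cluster size enforced *inside* the assignment step via a deterministic
minimal-cost repair, and outliers are then assigned to their nearest
medoid. One groupwise template is built per cluster and its LPVH label
is propagated back to each member. PAM uses best-of-`restarts`
restarts; restart r is seeded `seed + r` and cost ties break toward the
lowest sorted medoid set, so results are reproducible.

## 4. Segmentation network (`segmenter`, `nn`)

A 3D U-Net (default depth 5, 16 initial features, doubling per level;
two conv–BN–ReLU blocks per level, max-pool down, nearest-neighbour
up-sampling with skip concatenation) implemented from scratch in NumPy
with hand-derived backward passes, trained with Adam. The convolution
forward/backward kernels are numba-JIT compiled; a pure-NumPy
im2col/GEMM fallback is used when numba is unavailable, and a unit test
asserts both agree.

**Loss.** L = L_MD + λ·L_CE with λ = 1: soft multi-class Dice averaged
over the four *foreground* classes (ε = 1e-5) plus voxel-mean
cross-entropy over all five classes. The gradient through the softmax is
analytic and verified against finite differences.

**GA-aware augmentation.** Random flips (p = 0.5), rotations (±30°),
translations (±10 voxels) and isotropic scaling with GA-dependent
bounds:

    s_min(w) = max((0.9·V̄(18)/V̄(w))^(1/3), 1/1.5)
    s_max(w) = min((1.1·V̄(26)/V̄(w))^(1/3), 1.5)

so a subject of week w can be scaled to any plausible size between a
small 18-GW and a large 26-GW brain, never by more than 1.5× in either
direction.

**Training protocol.** Exactly `iteration_budget` Adam steps (default
100 epochs' worth, i.e. `100·ceil(n/batch)`), batch size 4, learning
rate 0.001 by default. With expert labels all subjects are used for
training; with atlas labels (free to produce) 10% of subjects are held
out and their loss is logged for monitoring. Inputs are z-scored per
volume. Post-processing at inference keeps the largest connected
component per foreground class.

## 5. Metrics (`metrics`)

Dice similarity coefficient (both-empty → 1.0), 95th-percentile
symmetric Hausdorff distance in mm (boundary voxels = foreground minus
its 6-connected erosion; undefined when a mask is empty → NaN with a
warning), and signed/unsigned relative volume differences
(V_pred − V_gt)/V_gt. Both Dice and H95 are verified against brute-force
oracles in the test suite.

## 6. Growth curves (`growth`)

Structure volumes come from post-processed segmentations (voxel count ×
voxel volume). Whole-brain volume is estimated by registering a
GA-matched brain-template mask to the subject with a similarity
transform (rigid + isotropic scale, mean-squares metric, moments
initialization) and counting warped-mask voxels; registration that fails
to improve on the identity raises instead of returning silently bad
volumes.

Volume-vs-GA curves are fitted per structure and per model tag by OLS
(statsmodels). A quadratic term is kept only when it is significant
(p < α = 0.05) *for every model tag* of that structure, otherwise the
fit is linear; degenerate zero-residual fits count as not significant.
Fits require ≥10 records spanning ≥4 distinct gestational weeks per
tag. 95% prediction intervals are computed from the stored coefficient
covariance and residual variance with the exact t-quantile.

## 7. Desk-scale problem sizes

The package's own evaluation (tests, acceptance script, examples) runs
on one CPU in minutes, so it uses reduced problem sizes as a deliberate
design choice: grids of 24³–64³ at 1.4–3.2 mm spacing instead of
160³ at 0.6 mm, U-Nets of depth 2–3 with 8 features instead of depth 5
with 16, and iteration budgets in the hundreds. Two consequences are
documented in the project notes and handled explicitly:

- At coarse spacing, early-GA CSPV and LPVH fall below a few voxels and
  are unlearnable for resolution reasons; training experiments therefore
  use the 22–26 GW range, while template, clustering and growth
  experiments keep 18–26 GW.
- With ~25× fewer optimizer steps than a full training schedule, the
  full-scale default learning rate (0.001) cannot leave the
  cross-entropy plateau; desk-scale experiments pass a larger learning
  rate explicitly. The `SegConfig` default remains the full-scale value.

## 8. Known limitations

- The U-Net is CPU-bound NumPy/numba; full-scale (160³, depth 5)
  training is out of scope on one CPU.
- Phantom appearance is far simpler than real neurosonography; absolute
  DSC/H95 values reported by the acceptance script characterize the
  pipeline on phantoms only and are not comparable to published values
  on clinical cohorts.
- Whole-brain estimation assumes the subject is already roughly aligned
  (it uses a similarity transform, not a full affine or deformable
  model).
- Hemisphere handling assumes a perfectly midsagittal plane at the
  central voxel plane of axis 0.
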