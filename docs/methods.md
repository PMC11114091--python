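# Methods

This note documents the models, estimators and synthetic-data choices behind
`periwater`, in enough detail to judge what a passing test suite does and does
not demonstrate.

## The signal model

Diffusion MRI attenuation in each voxel is modelled with two compartments:

    A_i = f_t · exp(−b_i gᵢᵀ D_t gᵢ) + (1 − f_t) · exp(−b_i d_w)

* `f_t` — tissue volume fraction; the free-water fraction is `fw = 1 − f_t`.
* `D_t` — symmetric positive-semidefinite tissue diffusion tensor (mm²/s);
  its fractional anisotropy is the free-water-corrected tissue FA (`FA_T`),
  its trace/3 the tissue mean diffusivity (`MD_t`).
* `d_w` — fixed isotropic diffusivity of free water at body temperature,
  3.0×10⁻³ mm²/s. The literature states the compartment as "free water at
  37 °C" without a number; the canonical constant is adopted and exposed in
  the configuration.

Attenuations `S_i/S_0` are fitted, with `S_0` the geometric mean of the b=0
volumes.

## The bi-tensor estimator

`fit_bitensor` runs a batched Levenberg–Marquardt least-squares over all
masked voxels simultaneously:

* `f_t` is box-constrained to `[ε, 1−ε]` (ε = 0.01) through a logistic
  transform; `D_t` is kept PSD through its lower-triangular (Cholesky) factor.
* Convergence per voxel: scaled parameter change < `tol` (default 1e-6) or
  relative cost decrease < `ftol` (default 1e-10), within `max_iter` (200)
  iterations. Voxels exhausting the budget keep their best iterate and are
  flagged, never aborting the volume. The Marquardt damping is diagonal-scaled
  and adapted per voxel (×1/3 on accepted steps, ×4 on rejections).

### Identifiability at a single shell, and the two regularizers

At a single b-value, `f_t` and `MD_t` trade off along a nearly flat valley of
the objective: a slightly "hotter" tensor mimics a larger free-water fraction.
Unregularized voxelwise fits on this package's own phantoms showed the
expected pathology (healthy-WM fw estimated 0.25 against a truth of 0.15 at
SNR 30, fw/MD error correlation ≈ −0.9 at SNR 10; identical under Gaussian
noise, i.e. not a magnitude-bias artifact). Two mechanisms address it:

1. **Tissue-MD anchor** (default on, weight 0.5): one extra residual
   `√w · (MD_t / md_anchor − 1)` per voxel, with `md_anchor` = 0.7×10⁻³ mm²/s
   (healthy cerebral white matter). One penalty row against ~64 data rows
   barely distorts well-determined voxels but selects a unique solution along
   the degenerate valley. Results are insensitive to the weight over at least
   0.2–2.0. This is the package's analogue of the fixed-diffusivity
   assumptions that published single-shell free-water estimators rely on; in
   real tissue whose MD departs far from the anchor (e.g. necrotic cores) it
   biases `MD_t` toward the anchor — a documented limitation.
2. **Spatial penalty** (`lambda_reg`, default 0): in outer cycles after the
   first, `f_t` is coupled to the 6-neighbor mean of the previous cycle's
   field through a penalty residual whose weight is `lambda_reg` relative to
   the median data curvature in `f_t`. It reduces voxelwise fw RMSE at low
   SNR (0.080 vs 0.092 at SNR 10 with `lambda_reg` = 0.1) but smooths across
   ROI boundaries; because the perilesional analysis averages 1-voxel-wide
   rings, smoothing halves the recovered lesion contrast, so the default
   leaves it off and relies on the anchor alone.

### Initialization

The default initialization profiles the objective over a 24-point grid of
tissue fractions: for each candidate `f`, the free-water term is subtracted
from the attenuations, the tissue tensor is fitted log-linearly, and the
candidate with the smallest full (data + anchor) residual wins. Profiling
across the valley avoids the systematic underestimation of lesion free-water
that a purely MD-based start produces at b = 1500 (the log-linear MD of a
mixture barely sees the fast-decaying water signal). The MD-heuristic
initialization `f_t = clip((d_w − MD)/(d_w − md_tissue_ref), ε, 1−ε)` remains
available (`init_mode="md"`) and as `init_freewater` in the public API.

`compute_fa` clamps negative eigenvalues to zero (logged) before the FA
formula and defines FA of the zero tensor as 0. Non-positive signals are
clamped to a configurable floor with a logged count.

## Perilesional shell construction

All morphology uses the 6-connected (face-adjacent) structuring element, so
one dilation step is exactly one voxel (2 mm) of city-block distance;
26-connectivity would break the "2 mm per iteration" correspondence along
diagonals. The order of operations is: mirror the lesion across the grid
midline (axis 0; an odd dimension is required so the reflection is an exact
involution) → subtract the ventricle mask from the mirrored lesion → grow
eight 1-voxel rings around each lesion mask (ring k = k-fold dilation minus
(k−1)-fold dilation) → remove the intersection of corresponding ipsi- and
contralateral rings from **both** sides → intersect the rings (not the lesion
ROIs) with white matter eroded by 2 voxels. Shell labels 2 mm … 16 mm name
the outer boundary distance of each ring.

ROI means are normalized contralaterally: `(ipsi − contra)/contra`, with the
ventricle-cleaned mirrored lesion as the lesion's reference. Empty ROIs and
zero contralateral means yield NaN (never ±inf) with a logged warning.

## The synthetic phantom and cohort

The phantom emulates the study conditions the analysis was designed for: an
isotropic 2 mm grid (default 31³), a single-shell acquisition of 64
spherical-Fibonacci directions at b = 1500 s/mm² plus one b = 0 volume, a
mirror-symmetric "brain" (ellipsoidal white matter, paired paraventricular
CSF spaces) and one ellipsoidal subcortical lesion strictly inside one
hemisphere. Baselines (healthy WM fw 0.15, FA_T 0.55, MD 0.7×10⁻³ mm²/s) are
configurable defaults for healthy white matter, not literature claims. Tissue
tensors are cylindrically symmetric with eigenvalues solving the FA formula
exactly at fixed MD and a principal axis that varies smoothly over the grid
(normalized gradient of a fixed smooth scalar field — no claim of realistic
fiber geometry). Noise is Rician: the magnitude of `(A·s0 + n₁, n₂)` with
Gaussian channels of σ = s0/SNR (default SNR 30).

### Effect structure

The lesion effect on the normalized scale is
`delta(measure, t, k) = base · mult[t] · decay[t]^k` for ring k (k = 0 is the
lesion itself), applied ipsilaterally only; the contralateral hemisphere
holds baseline values exactly. Defaults encode the reference study's reported
trajectories:

* free-water: base +0.41 with per-visit multipliers (1, 2.707, 5.073, 6.122),
  i.e. lesion effects +41/+111/+208/+251 %; per-visit ring decay
  (0.591, 0.181, 0.209, 0.435), calibrated to the reported ratio of the 2 mm
  shell to the lesion effect — the nearest, always-significant shell carries
  the gradient the analysis keys on;
* tissue FA: base −0.343 with multipliers (1, 1.087, 0.755, 0.534) — the
  1-month minimum — and ring decay (0.29, 0.545, 0.62, 0.64) calibrated so
  the across-ROI mean trajectory matches the reported means, because for
  FA_T the salient finding is the widespread spatial extension at 1 month.

A single scalar decay cannot express that the spatial gradient steepens and
relaxes over visits, which is why the decay is per-visit and per-measure
(scalars are accepted and broadcast).

### Cohort design

Default: 27 enrolled subjects, visits at 3–5 / 30–40 / 85–95 / 340–380 days
post-stroke, retention exactly 26/21/19/19 with monotone dropout (a subject
who misses a visit misses all later ones — the simplest pattern consistent
with those counts; note it implies one enrolled subject with no scans).
Among subjects followed to 3 months, `round(0.72·m)` lesions shrink by
construction. Covariates (age ≈ N(66.7, 11.6²), 59% male, log-normal lesion
volumes, NIHSS/UEFM/NHP/grip trajectories that improve over visits) are
plumbing with plausible ranges, carried so the adjustment terms in the models
are exercised; they have zero true effect on the imaging measures.

Measure variability on the normalized scale is homoscedastic by design
(the study tables imply strongly lesion-dominated heteroscedasticity; the
scalar-SD simplification is deliberate): between-subject SD 0.15 (fw) / 0.03
(FA_T), within-subject residual SD 0.30 / 0.06, chosen once as pooled
approximations of the confidence intervals printed in the reference tables
(whose pooled marginal SD is ≈ 0.45 for fw — the defaults sit on the
conservative-noise side of that).

Two simulation tiers share this design: `simulate_cohort` +
`make_truth_maps` + `simulate_dwi` produce full per-scan imaging phantoms;
`simulate_measures` draws the ROI-measure table directly (truth delta +
subject effect + residual), which is what replicate-heavy statistical
studies use.

### What the generator does not emulate

Real anatomy and fiber architecture, registration and segmentation error,
distortion/motion/eddy artifacts and their preprocessing, partial-volume
mixtures at tissue interfaces, per-location heteroscedasticity, non-monotone
missingness, and any true covariate–imaging associations. Passing tests
demonstrate internal consistency of the estimators and statistics under the
stated model, not performance on real scanner data.

## Statistics

* **Per-ROI tests**: two-sided one-sample t-tests of the normalized measures
  against zero per location × visit; Cohen's d = mean/SD (n−1). Zero-variance
  cells raise rather than emit a p-value. No multiplicity correction across
  the ROI×visit grid (matching the analysis plan being reproduced).
* **Longitudinal model**: REML linear mixed model with crossed random
  intercepts for subject and measurement location (implemented as variance
  components over a single grouping), fixed effects: visit (dummy-coded
  against the first), lesion volume, age, sex (male indicator), and
  days-since-stroke z-scored within visit (degenerate groups map to 0 so the
  covariate stays defined). Omnibus visit test: Wald chi-square on the three
  visit coefficients (likelihood-ratio available via config). Missing rows
  are dropped per model with a logged count, never imputed.
* **Post-hoc pairwise visits**: single-step ("Tukey") adjustment on the six
  pairwise contrasts. The joint null of the contrast t-statistics is
  multivariate t with the correlation induced by the coefficient covariance
  (rank 3 for 6 contrasts, hence singular); the equicoordinate probability is
  estimated by seeded Monte Carlo (2×10⁵ draws) on an eigen-factor of that
  covariance, with residual (n − p) degrees of freedom. Satterthwaite dof
  were considered and skipped: at ~750 residual dof the t and normal scales
  are indistinguishable, and the reference analysis does not state its dof
  method.
* **R²**: variance-partition convention — marginal = fixed-effect variance
  over (fixed + random + residual), conditional adds the random components.
* **Cross-sectional models**: per visit, subject random intercept, location
  fixed with the lesion as reference, same covariates (minus the degenerate
  days z-score).
* **Correlations**: Spearman with midrank ties; exact two-sided permutation
  p for n ≤ 9 (full enumeration), t-approximation above. Constant vectors
  yield NaN with a warning.
* **Adjusted regressions**: OLS with two-sided Wald p; rank-deficient designs
  raise an error naming the collinear columns.
* **Power**: noncentral-t power of the two-sided one-sample t-test,
  ncp = d·√n.
* The perilesional summary used in correlation analyses is the unweighted
  mean of the eight shell means (voxel-weighted available via config).

### Statistical power of the default design

One structural property worth knowing: because the lesion trajectory is much
steeper than the shell trajectories, the visit × location interaction is
absorbed into the mixed model's residual (the model has no interaction term),
inflating visit-contrast SEs to ≈ 0.044 on the normalized fw scale — closely
matching the reference analysis's ≈ 0.05. At the default effect sizes the
3-month-vs-1-month contrast (true across-location difference ≈ 0.14) then has
only ~75% single-step-adjusted power, so the full "every pair significant
except the first two visits" pattern reproduces in roughly three quarters of
replicate cohorts, not more — a power limit of the design being emulated, not
an estimator defect.

## Numerical choices and degenerate inputs

* Fit tolerances: `tol` 1e-6, `ftol` 1e-10, `max_iter` 200, LM damping in
  [1e-12, 1e12]; voxels saturating the damping are frozen in place.
* Negative tensor eigenvalues: clamped to zero for FA/MD (logged); Cholesky
  factors obtained after flooring eigenvalues at 1e-9 mm²/s.
* Gradient tables: directions are re-normalized on read when the norm errs by
  more than 1e-3 (warned); fewer than 6 non-collinear directions raise.
* Mirroring requires an odd left–right dimension; real data not aligned to a
  voxel midline must be mirrored in a symmetric standard space upstream.
* Empty ROIs, zero contralateral means, zero-variance cells, singular mixed
  models: missing sentinels / flagged results, never silent numbers.
* Pipeline runs are reproducible from config + seed alone; every stochastic
  step (direction lattice rotation, noise, cohort draws, Tukey Monte Carlo)
  is seeded.

## Problem sizes used by the test suite

The suite exercises the default 31³ phantom where geometry matters and a 21³
phantom (≈3,700 brain voxels) where fit runtime dominates; replicate studies
use 100–200 simulated cohorts at the measures level and 2–3 noise seeds per
visit through the full imaging chain. These sizes were chosen as the smallest
that leave the statistical assertions limited by the design rather than by
Monte-Carlo error.
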