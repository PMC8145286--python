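# Methods

## Model and assumptions

`voxstate` assumes cortical activity during a task is, to first order, a
linear mixture of task-variable timecourses: **Y = XB + E**, with **Y**
(TRs × voxels) the preprocessed BOLD matrix, **X** (TRs × variables) the
task design, and **E** everything else (non-task networks, physiological
fluctuations, scanner noise). The task-related state space is the span of
the task-variable weight maps after two regularizing steps:

1. the weight maps **B** (ordinary least squares; OLS is adequate because
   variables ≪ TRs) are projected onto the top-*L* principal axes of **Y**
   (**B**<sub>L</sub> = **U**<sub>L</sub>**U**<sub>L</sub><sup>T</sup>**B**),
   discarding weight structure that accounts for little activity variance;
2. QR factorization of **B**<sub>L</sub><sup>T</sup> orthonormalizes the
   (generally correlated) weight maps into a basis **Q**<sub>S</sub> with
   one axis per task variable.

Activity at each TR projects to **p**<sub>i</sub> =
**y**<sub>i</sub>**Q**<sub>S</sub>. The method is supervised: the quality
of the space depends entirely on how well the chosen task variables
describe the task. It assumes states are approximately Gaussian clouds in
the recovered space when evaluated with the CSI, and that voxel noise is
stationary enough for a single z-scoring to be meaningful.

QR orthonormalization is order-dependent: axis *k* is the part of variable
*k*'s denoised weight map orthogonal to variables 1..*k*−1. Cross-projection
tables therefore need not be symmetric — a state can project strongly onto a
later variable's axis while the reverse projection vanishes. This mirrors
the non-reciprocal relationships the method is designed to expose.

## Preprocessing

Low-frequency drift is estimated per voxel with a Savitzky-Golay filter
(window 240 s, polynomial order 3) and subtracted; voxels are then
z-scored. Conventions:

* window length in samples = `round(window_seconds / tr_seconds)`, forced
  odd (the filter requires odd windows);
* detrending runs independently within each acquisition run, with the
  filter's own polynomial fit at segment edges (no wrap/reflection across
  run boundaries); a run shorter than the window is a configuration error;
* variance uses the **population** convention (divide by N) everywhere —
  z-scoring, cluster covariances — chosen once and applied consistently;
* columns with variance below 1e-12 are zeroed and reported, not dropped,
  preserving voxel indexing.

A task variable that is constant within every run (e.g. a per-run
condition indicator) is annihilated by per-run detrending; its axis then
reflects only interaction/gain structure surviving in the data. This is a
property of the preprocessing, not a defect of the subspace recovery.

## HRF deconvolution

The FIR encoding model concatenates each feature delayed by 1, 2, 3 and
4 TRs (no 0-delay term; the BOLD response is delayed) in feature-major,
delay-minor column order. Ridge weights are selected per voxel by held-out
Pearson correlation over 10 contiguous temporal folds (contiguous, not
shuffled, to respect BOLD autocorrelation), from a default grid of 10
log-spaced penalties in [1e-2, 1e4]; a shared-penalty mode
(`per_voxel=False`) is available for speed. Final weights are refit on all
data at the selected penalty. Averaging the FIR weights over delays gives
one selectivity weight per feature and voxel; multiplying the feature
timecourses by these averaged weights reconstructs activity with the
hemodynamic delay removed. Ridge solutions for the whole penalty grid come
from a single SVD per fold. Penalties must be positive: a tiny floor
(1e-8) rather than 0 keeps singular designs solvable.

## State-space numerics

* **Centering.** Design columns are mean-centered and an (discarded)
  intercept absorbed before OLS, so binary {0,1} indicators become signed
  axes — presence projects positive, absence negative.
* **Denoiser.** `n_components` defaults to 24, exposed as a knob, with an
  alternative variance-threshold mode. PCA uses the matrix as given (the
  columns are already z-scored); no extra row-centering. The dense
  projector **D** (voxels × voxels) is never formed — with ~50,000 cortical
  voxels it would need ~20 GB — all products use
  **U**<sub>L</sub>(**U**<sub>L</sub><sup>T</sup>·).
* **Rank checks** are tolerance-based at 1e-10 relative to the largest
  singular value; rank-deficient designs and weight matrices raise errors
  naming the implicated variables.
* **Sign convention.** Basis column *k* is flipped, if needed, so its inner
  product with denoised weight row *k* is positive (equivalently, the
  diagonal of **R** is made positive).

## Quantification

* **Cluster fits.** Per-state mean and population covariance, shrunk
  toward a scaled identity: `(1−λ)S + λ(tr S/d)I`, default λ = 0.05 —
  clusters can be small relative to 9 dimensions. Labels with fewer than
  `dims + 2` points are flagged.
* **JSD.** No closed form exists for Gaussians, so a seeded Monte-Carlo
  estimator draws 10⁵ samples per Gaussian (default), scores the
  equal-weight mixture by log-sum-exp, and uses base-2 logarithms so the
  supremum is exactly 1; estimates are clipped to [0, 1]. Sorting the pair
  canonically before sampling makes the estimator *exactly* symmetric. A
  1-D quadrature oracle in the tests bounds the MC error below 0.005 at
  10⁵ samples. Non-positive-definite covariances raise an error pointing
  to the shrinkage parameter.
* **CSI** is the mean of all unordered pairwise JSDs, computed in the full
  state space (3-D or 9-D), with per-pair seeds derived from one seed.
* **Decoding.** Nearest cluster = Euclidean distance to the centroid
  (a Mahalanobis option exists behind `metric=`); exact ties resolve to the
  lexicographically first label. Cross-validation refits the whole pipeline
  (OLS, PCA, QR, centroids) inside each training fold. Folds are contiguous
  temporal blocks; if a block split leaves a state absent from some
  training fold, the folds are rebuilt as a seeded label-stratified shuffle
  (or the run errors, per `on_missing_class`). Chance = 1/K is recorded.
* **Multi-label TRs.** States need not be mutually exclusive. A TR
  contributes to every cluster it is labeled with (CSI, cross-projection,
  centroids); a classified TR counts as correct if the prediction matches
  *any* held label; the confusion matrix counts a TR once per held label,
  so row sums equal per-label test counts and balanced accuracy remains
  mean per-class recall. TRs with an empty label set are ignored by the
  metrics but still inform the subspace fit through **X**.
* **Permutation tests** shuffle labels per TR (or in contiguous
  same-label blocks) and re-run the full analysis; one-sided p uses the
  add-one convention `p = (1 + #{null ≥ obs}) / (1 + n)`, so p ∈
  (0, 1] and the smallest attainable p is `1/(n+1)`. Default 10,000
  permutations; reporting p below 1e-4 requires raising `n_permutations`
  accordingly, and Bonferroni-corrected cell tests in `cross_projection`
  need `n_permutations ≳ n_cells/alpha` to be able to reject at all.
* **Empirical chance levels** (`permuted_label_chance`) permute all labels,
  fit centroids on the first 80% of TRs with the permuted labels, and score
  the remainder against the same permuted labels — the decoding analysis
  run on its own null. Averaged over permutations this estimates 1/K;
  naive alternatives (permuting only training labels and scoring against
  the true test labels) are biased away from 1/K whenever class counts are
  unequal, because small permuted classes have noisy centroids that
  capture outlying test regions.

## Synthetic generator

The generator produces the statistical world the model assumes — activity
= binary task timecourses × planted weight maps, smoothed by a
double-gamma HRF (peak 6 s, undershoot 16 s, ratio 1/6; `hrf="delta"`
disables smoothing), plus sinusoidal low-frequency drift (two components
per voxel, periods 500–1200 s) and white Gaussian noise. SNR is defined as
planted-signal variance over noise variance per voxel, averaged across
signal-carrying voxels, after HRF smoothing. State chains use
`P(on_t) = ρ·on_{t−1} + (1−ρ)·m` with `ρ = max(0, 1 − 1/(dwell·(1−m)))`,
giving the requested marginal exactly, mean on-dwell ≈ `dwell` TRs, and
independent draws at `dwell = 1`.

Default study conditions: 3000 TRs (TR = 2 s), 2000 voxels, weight maps on
sparse overlapping supports (60% of voxels per variable, half shared),
dwell 10 TRs, drift amplitude equal to the mean signal SD, SNR 50. The SNR
default was calibrated once so that the 24-component denoiser captures
0.6–0.8 of post-preprocessing variance on the attention scheme (measured
≈ 0.67), matching the regime the method expects on real cortical data; the
game scheme, whose nine fast state chains place signal everywhere, sits
higher (≈ 0.95).

What the generator does **not** emulate: spatial autocorrelation between
voxels, physiological (cardiac/respiratory) noise, motion artifacts,
non-task low-rank background networks, HRF variability across voxels, and
non-linearities. Passing tests therefore show the pipeline is correct
under its own model assumptions and recovers planted structure at
realistic noise levels — not that real fMRI data satisfies those
assumptions.

The attention scheme encodes the 3-level attention condition as one signed
column (+1 attend category A, −1 attend category B, 0 passive); the coding
of a categorical condition on a single axis is genuinely ambiguous, and
users may substitute any coding (or expand to indicators) by supplying
their own design. The attention-like gain multiplies the presence columns
during attended blocks, the generator's analogue of attentional
enhancement of task-relevant representations; CSI increases with the gain.

## Benchmark problem sizes

The test suite and `scripts/acceptance.py` use scaled-down instances
chosen as the smallest sizes at which each property is statistically
clean: chance levels on 3000 TRs × 400 voxels with 1000 permutations;
subspace recovery on 2000 × 2000; the gain effect on 20 seeds of
900 × 300 with 8000-sample JSDs; decoding on 1200 × 400 with 10 folds.
The high-SNR decoding benchmark uses a delta HRF and zero drift — it
isolates the pipeline's ability to decode separable states, and
hemodynamic smearing of state boundaries is a property of the measurement,
not of the estimator under test.

## Known limitations

* The supervised basis inherits any misspecification of the task
  variables; it cannot discover states that were not labeled.
* CSI depends on the Gaussian cluster approximation and on the MC sample
  count; values from different `mc_samples` are comparable only
  approximately (MC standard error, not bias, dominates above ~10⁴).
* With strongly correlated task variables the QR step concentrates shared
  variance on whichever variable comes first in the declared order.
* Per-run detrending removes run-constant task variables (see above).
* The per-voxel ridge path holds all penalties' weight matrices in memory;
  for very large voxel counts use the shared-penalty mode.
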