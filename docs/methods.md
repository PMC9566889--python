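# Methods

## Model and pipeline

`petstratify` classifies spatially aligned 3-D uptake volumes with a
soft-margin linear SVM over masked voxels. The pipeline assumes inputs are
already co-registered to a common space (no resampling or warping is
performed anywhere; affines are carried through untouched). Preprocessing is
**smooth, then scale**: each volume is smoothed with a separable Gaussian
(σ per axis = FWHM / (2√(2 ln 2)) / voxel size) and then proportionally
scaled so its mean over the brain mask equals a grand-mean target. The
whole-brain mean is always computed over an explicit mask, never over the
rectangular grid, whose background would dilute it arbitrarily. Masked
voxels are flattened in ascending (k, j, i) lexicographic order; this order
is recorded with every feature matrix and model.

The classifier is trained in the dual on the kernel
k(x, y) = x·y / s² + δ (kernel scale s, offset δ) with per-class costs taken
from a 2×2 misclassification-cost matrix and box constraint C. Because the
dual carries the equality constraint Σαᵢyᵢ = 0, a constant kernel offset
cannot change the optimal dual variables; its contribution is nevertheless
absorbed exactly into the exported bias. The solved hyperplane is exported
in primal form (per-voxel weight map + bias). A subject score is
**w**·**x** + bias — the bias is included so that the score's sign equals
the classifier output; a score of exactly 0 is classified as stable (the
positive class is strictly positive scores). The contract is the
optimization problem, not a particular solver: the production path (libsvm
via scikit-learn on a precomputed kernel) is verified against an
independent dense SLSQP quadratic program (`petstratify.reference`) to
better than 1e-4 relative score agreement on random small instances. When
an instance has no free support vectors the bias is determined only up to a
KKT interval; the reference uses the interval midpoint, the same convention
libsvm applies, so the comparison is well-posed even on degenerate inputs.

**Outlier fraction.** The robust-training option is implemented as a single
trimming pass: fit, rank training points by hinge slack, drop the top
⌈fraction·n⌉ among points with positive slack, refit once (never dropping a
whole class). With fraction 0 the plain SVM is recovered exactly. This is a
documented, reproducible interpretation of "outlier fraction" for a
soft-margin SVM; it is deliberately simple and testable.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| smoothing FWHM | 8 mm | spatial scale of the metabolic signal; matches common PET practice |
| scaling target | 50 | grand mean after proportional scaling (conventional PET value); affects scores only by a constant factor |
| outlier_fraction | 0.05 | fraction of highest-slack training points trimmed before the refit |
| misclassification cost | [[0,1],[1,0]] | symmetric unit costs; asymmetric costs reweight per-class C |
| kernel offset δ | 0.1 | constant added to every inner product; provably inert for exact solvers (absorbed into bias) |
| kernel scale s | 1 | inner-product normalization |
| box constraint C | 1 | soft-margin penalty |
| max iterations / tolerance | 10⁶ / 1e-8 | optimizer budget; non-convergence raises, it is never silently accepted |
| k (cross-validation) | 10 | stratified folds with seeded shuffling; k is reduced with a warning if a class has fewer members |

Cross-validation is stratified by default because with ~40 subjects and
k = 10 unstratified folds can be single-class; it can be switched off.
Metrics come from the pooled out-of-fold confusion table rather than
per-fold averages, so one sensitivity/specificity pair describes the
cross-validated model. AUC is the Mann–Whitney form (ties count ½).

## Permutation inference on the weight map

10,000 label permutations is the documented production setting; tests and
the acceptance script use 200–500, which keeps full-refit suites at desk
scale on the default grid. Permutations shuffle labels (class sizes
preserved) and retrain with identical hyperparameters; exceedance counts
are streamed, so null weight maps are never stored.

**Statistic.** By default each weight map is L2-normalized before the
per-voxel comparison, i.e. the statistic is |w_v| / ‖w‖₂. The global scale
of a soft-margin SVM weight vector is the inverse margin: a strongly
separated labeling yields uniformly *small* weights and a label-shuffled,
barely separable one uniformly *large* weights. Comparing raw magnitudes
therefore loses all power exactly when the class signal is strong (on
strongly planted synthetic cohorts the raw comparison yields p ≈ 1 at every
voxel), while on weakly separable data — the regime of real cohorts — the
two statistics nearly coincide. Normalization removes the scale nuisance
and asks the scientifically intended question ("*where* does discriminative
weight concentrate?"); under the global null the true and permuted models
remain exchangeable for any statistic, so calibration is untouched
(verified: the fraction of null voxels with p < 0.05 stays at ≈0.05). The
raw comparison is available via `normalize=None`.

**Tie handling.** Ties count as exceedances (≥), so p is conservative and
the minimum attainable p is 1/n rather than 0; a strict-inequality variant
and an add-one (b+1)/(n+1) estimator sit behind flags.

**No multiplicity correction.** Inference is per-voxel and uncorrected —
thresholding ~2×10⁴ voxels at p < 0.05 admits ~5% of null voxels by
construction. The thresholded map is a descriptive pattern, not a
family-wise-error-controlled localization.

## Pattern similarity

Pearson correlation over mask voxels, with a p-value from phase-randomization
surrogates of the first map: Fourier amplitude spectrum (hence spatial
autocorrelation) preserved to numerical precision, phases drawn from the
spectrum of white noise, mask re-applied, mean/variance re-matched. The test
is two-sided on |r| and uses the add-one estimator, so p ∈ (0, 1] with
minimum 1/(n_surrogates+1). Variogram-matched surrogates and surface-based
spin tests are out of scope; phase randomization is a stationary
approximation — it matches overall smoothness, not nonstationary local
autocorrelation structure.

## Synthetic cohorts: what they emulate, and what they do not

The generator plants class-specific multiplicative effects (±amplitude ×
template inside spheres) on a smooth brain-like phantom (ellipsoidal mask,
outer shell ≈ 1, elevated center), adds a per-subject lognormal global
uptake factor (median 1, log-SD 0.05 by default — the tracer-dose nuisance
that proportional scaling is designed to remove, made explicit so tests can
prove the normalization works) and i.i.d. Gaussian noise inside the mask
(SD 0.1 in template units by default). Default cohort sizes are 20 + 23,
matching a realistic two-class training cohort at this grid scale; the
default pattern is two posterior hypometabolic and three anterior/deep
hypermetabolic spheres covering ≈11% of the mask, a caricature of a
conversion signature. The default grid (32×40×32 at 4 mm, ≈1.8×10⁴ mask
voxels) keeps permutation suites fast; it is configurable upward. The
generator emits raw-like (unsmoothed) volumes; the preprocessing stage owns
the 8 mm smoothing.

Not emulated: PET physics (scatter, attenuation, partial volume),
anatomical atlas fidelity, spatially correlated or heteroscedastic noise,
registration error, scanner differences, longitudinal trajectories.
Passing tests therefore demonstrate the *pipeline's* correctness,
calibration and power under known ground truth — not clinical performance
on real scans.

## Numerical choices

- **Smoothing boundaries:** truncated-kernel convolution (6σ support)
  renormalized by the convolved grid indicator, so constants are preserved
  everywhere; interior voxels match a dense full-kernel oracle to <1e-6.
- **Scale invariance:** proportional scaling removes a per-subject global
  factor exactly in exact arithmetic; in floating point the cancellation is
  bit-exact for power-of-two factors (binary rounding commutes with exact
  power-of-2 scaling) and holds to ~1e-12 relative for arbitrary factors.
- **Model persistence:** weight maps are stored as float64 NIfTI (images as
  float32, masks as uint8) so that reloaded models reproduce subject scores
  to ≤1e-10 relative; scalar metadata lives in a human-readable JSON
  sidecar, and application refuses any cohort whose preprocessing record
  (FWHM, target, mask checksum) differs from the training record.
- **Determinism:** phantoms are analytic (no RNG); cohorts, folds,
  permutations and surrogates are reproducible from explicit seeds; SVM
  training is deterministic for fixed input order.
- **Trimming ties** are broken by stable sort on slack, so trimming is
  deterministic too.

## Test problem sizes and statistical bands

Calibration tests use the default coarse grid: null-calibration runs 5
zero-effect cohorts (20+20) × 200 permutations; recovery uses one 25+25
cohort × 500 permutations; monotonicity averages 10-fold CV accuracy over
10 seeds per amplitude in {0, 0.05, 0.15, 0.30}. The null-calibration band
([0.02, 0.08] per cohort, [0.035, 0.065] for the 5-seed mean) is derived
from the attainable level 10/201 with an effective number of independent
voxels of ≈2.2×10³ (mask voxels divided by the smoothing kernel volume,
FWHM = 2 voxels per axis) and a 2× variance inflation for cross-voxel
dependence through the shared permutations. The zero-effect CV band
(|mean − 0.5| ≤ 0.08 over 20 cohorts) is three binomial SEs of the 400
pooled predictions plus slack for fold dependence.

## Known limitations

- Linear kernel, two classes, no probability calibration, no feature
  selection, no nested hyperparameter tuning.
- The outlier-fraction semantics are a documented single-pass trimming
  approximation, not a reimplementation of any particular solver's internal
  robust handling.
- Uncorrected per-voxel permutation inference (by design; see above).
- The similarity null is stationary phase randomization, not a
  variogram-matched surrogate.
- Synthetic validation only: no claim about real-scan performance follows
  from these tests.
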