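# Methods

This note documents the models, numerical choices and open design decisions
behind `striatome`. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Synthetic phantom model

The imaging phantom is an *uptake* model, not a physics model: no
projection/reconstruction, attenuation or scatter is simulated. An ideal
volume holds a uniform background (default 10 counts) and two striatal
bodies whose voxels carry `background × uptake_contrast`. Bodies are
ellipsoids with an optional comma bend (the lateral centre drifts with the
squared normalised anterior-posterior coordinate), mirrored at ±13 mm about
the midline with semi-axes (7, 16, 9) mm on a 48×56×64 grid at 2 mm
isotropic spacing — sized so both bodies fit the standard (22, 28, 40)
analysis crop. The ideal image is blurred with a Gaussian point-spread
function (default 6 mm FWHM, the resolution class of clinical SPECT) and
then corrupted with Poisson count noise (scale = counts per intensity unit;
a Gaussian additive option exists). Ground-truth masks are defined
*pre-noise* as each body's blurred signal thresholded at 50 % of its own
plateau: an unambiguous, threshold-free truth for Dice scoring that
coincides with the geometric support at zero blur.

What this emulates: focal high-uptake structures over noisy background with
scanner-class blur. What it does not: anatomical background structure
(scalp, occipital uptake), reconstruction artefacts, inter-subject anatomy.
Passing segmentation tests therefore demonstrate correctness of the
operator chain on well-posed inputs, not clinical robustness.

## Synthetic cohort model

The clinical table has 59 columns: named demographic/cognitive/motor/
autonomic scales with plausible means and spreads (age ~ N(61.11, 9.93),
sex ~ Bernoulli(119/297), baseline MoCA ~ N(27.1, 2.3), HVLT, UPDRS parts,
sleep/mood scales, binary genetic-risk markers), padded to 59 with standard
normal covariates standing in for the long tail no public source itemises.
The binary year-4 outcome is drawn from a logistic model over
*population-standardised* features (default: intercept −0.5, age +0.5,
baseline MoCA −1.0, HVLT total −0.6, UPDRS-III +0.4; ≈ 40 % abnormal
prevalence). A year-4 MoCA score is then drawn on the realised side of the
26-point cutoff, so the labels equal the deterministic cutoff rule applied
to the returned scores, while the outcome *probability* follows the stated
logistic law — both properties are tested (binomial CIs, maximum-likelihood
refit recovery).

Imaging and outcome connect through `generate_labeled_phantoms`: normal
subjects receive a higher uptake contrast than abnormal ones (pipeline
default 3.4 vs 2.8 with 15 % log-normal per-subject jitter). The jitter
makes the imaging signal informative but weaker than the clinical one —
the regime the analysis is designed for. Tests that need perfectly
separable classes pass explicit contrasts (4.0 vs 2.0) with zero jitter.

## Segmentation chain

Twelve deterministic steps (enhance ×5, filter, sum, threshold, clean,
halve, assemble, QC). Choices the method description leaves open:

* **Contrast raise** (steps 3 and 5): linear stretch of [1st percentile,
  maximum] onto [0, 1]. Anchoring the top at the true maximum matters: a
  high-percentile anchor clips the small striatal plateau and amplifies the
  background floor (the striata occupy ~2 % of the crop).
* **CLAHE** (step 2): `skimage.exposure.equalize_adapthist` per slice,
  clip limit 0.005, tile grid 4. Each slice's output is rescaled back to
  its pre-CLAHE peak so slices without striatal signal stay dim relative to
  the uptake plateau; without this, per-slice equalisation lifts empty
  slices to full range and the global threshold floods the crop.
* **Order-statistic filter** (step 6): rank defaults to the median,
  ⌈window²/2⌉ with window 3; the filter family is fixed, the rank is not.
* **Threshold** (step 8): inclusive `≥ 0.40 × max`; the boundary convention
  is unstated, ≥ is fixed and tested.
* **Crop box** (step 4): fractional per-axis ranges (default 20–80 % of the
  grid), a configuration constant rather than atlas knowledge.
* **Closing** (step 9): 2D disk, radius 2, per slice.
* **Halving** (step 10): cut at the lateral midpoint; for odd widths the
  midplane column goes to the *left* output (arbitrary, fixed, tested).
  Lower lateral indices are the subject's left.
* **"Less affected" hemisphere**: the chain tags the hemisphere with the
  higher mean uptake as less affected; it does not attempt a sub-ROI
  boundary, which no operator definition supports.

The chain has no stochastic step; Dice ≥ 0.7 against ground truth across a
20-phantom default suite is the acceptance bar, and mask monotonicity under
a rising threshold fraction is a tested invariant.

## Radiomics

Discretization defaults to fixed-bin-number with 64 bins over the in-ROI
range (maximum assigned to the top bin); constant ROIs map to a single
level and are flagged degenerate, not failed. Texture matrices are computed
in 3D: co-occurrence and run-length over the 13 unique directions with two
aggregations each (feature-then-average `avg`, merge-then-feature `mrg`),
zones by 26-connectivity, distance zones with taxicab distance to the ROI
border (border voxels = 1, array edge counts as outside), grey-tone
difference and dependence (α = 0) over 26-neighbourhoods. Every matrix
builder is tested against brute-force enumeration on small integer arrays.

The inventory is fixed at 215 names: 29 shape, 20 first-order,
30 intensity-histogram, 50 CM (25 × 2 aggregations), 32 RLM (16 × 2),
16 SZM, 16 DZM, 5 NGTDM, 17 NGLDM. Where the IBSI reference list is shorter
than a family's target count (first-order 18, intensity histogram 23), the
list is extended with standard distribution statistics (standard deviation,
sum, energy, RMS, 25th/75th percentiles, mode probability) to reach the
fixed counts; the names are stable and the mapping is the
`striatome.radiomics.features` name lists themselves. Shape features follow
the IBSI morphology family; the oriented bounding box is PCA-aligned and
the enclosing ellipsoid is the Khachiyan minimum-volume ellipsoid of the
hull points (both standard approximations); ellipsoid surface areas use the
Thomsen p = 1.6075 formula; Moran's I / Geary's C use inverse-distance
weights with deterministic thinning above 1 500 voxels to bound the
quadratic cost.

Pruning drops variance ≤ 1e-12 columns, then greedily keeps the first of
any pair with |Pearson r| ≥ 0.95 in column order (thresholds are
configuration; none are published).

## Neural networks

No deep-learning framework is part of the dependency set; both networks run
on a compact numpy engine (`striatome.nn`) with 3D convolution implemented
as one (F, C) × (C, N·V) matrix product per kernel offset — BLAS-bound
without the k³ im2col memory expansion — plus max-pool (floor rounding,
trailing odd slices dropped), nearest-neighbour up-sampling with
edge-replication to the exact encoder counterpart shape, batch-norm
(running statistics seeded from the first batch so short trainings retain a
sane inference mode), inverted dropout, dense layers, LeakyReLU/ReLU,
numerically-stable sigmoid + BCE on logits, and Adam. All parameter
gradients are finite-difference tested.

**Autoencoder**: encoder 3 × {conv 3³ → LeakyReLU(0.1) → max-pool 2},
channels 16/32/64; decoder mirrors with up-sampling and a final 1-channel
reconstruction convolution; inputs are per-volume min-max scaled to [0, 1].
A 22×28×40 input pools to 11×14×20 → 5×7×10 → 2×3×5, so the bottleneck is
2·3·5·64 = 1920 features (`df_0001`…). The bottleneck dimensionality is
architecture-derived and reported at build time, not hard-coded: no integer
channel width reaches the externally quoted 5375 from this input shape
under three 2× poolings, so the reported value is treated as
configuration-dependent. Deep features keep columns with population
standard deviation strictly > 0.25; the count that survives is
data-dependent. In the pipeline, if fewer than 2 survive (phantom
bottlenecks can be flatter than clinical data), the 50 most variable
features are kept instead and the manifest records the substitution.

**CNN**: three {conv 3³ → max-pool stride 2 → ReLU → batch-norm} blocks
with filters 32/64/64 (the third block's width is underdetermined by the
description "32 and 64 filters"; it is configurable), flatten → dense 256 →
dropout 0.30 → dense 2 with sigmoid outputs and BCE on one-hot targets.
The unusual activation-after-pooling order is implemented as specified,
with a `conventional_order` switch (conv → BN → ReLU → pool). The layer
manifest enumerates 13 layers (3 conv + 3 pool + 3 BN + flatten + dense +
dropout + output).

## Benchmark protocol

Outcome binarization reads the cutoff strictly: MoCA > 26 is normal, ≤ 26
abnormal (26 itself is formally unassigned by the verbal rule; strict-
greater is fixed and the cutoff configurable). The protocol is an outer
stratified 80/20 hold-out split plus 5-fold stratified CV on the 80 %.
Inside each fold, the z-scoring parameters, ANOVA F-scores, selected top-k
set, tuned hyperparameters and the fitted model derive from that fold's
training portion only (leakage-safe; per-fold selection is the safe reading
of an ambiguous description). Each fold model is scored on its held fold
(CV accuracy) and on the single hold-out set; the hold-out "mean ± std" is
the spread of the five fold models on that one set. Ties in selection break
to the earlier column; best-cell selection is argmax mean CV accuracy with
ties to smaller k.

Tuning offers `bayesian` (Gaussian-process expected improvement over a
small enumerated space, Matérn ν = 2.5, budget 25), `random` and `none`;
all deterministic under the seed. The pipeline default is `none` — on
60-subject synthetic cohorts tuning shifts accuracies within noise while
multiplying runtime.

Statistical checks: permutation-null accuracy is compared to the binomial
95 % CI of 0.5 computed at the number of scored held-out samples (320 for
n = 400); the paired t-test returns (0, 1) for identical fold vectors and
an infinite-t/zero-p sentinel for constant nonzero differences.

## Problem sizes and determinism

Test and acceptance problem sizes are chosen for complete desk-scale runs:
20-phantom segmentation suites; n = 400 tabular cohorts; 20-volume
autoencoder trainings (30 epochs in the sanity check, 15 in the acceptance
script); CNN protocol runs on 60 phantoms at 3–4 epochs (the separable
phantom classes converge within 2 epochs); end-to-end determinism on
n = 28 with shortened trainings. One global seed derives all stage seeds
via `numpy.random.SeedSequence`; with single-threaded BLAS two runs are
bit-identical, which the acceptance suite verifies on the emitted CSVs.

## Known limitations

* Phantoms lack anatomical background; segmentation robustness to real
  anatomy is untested by construction.
* Radiomics values follow IBSI definitions but are not benchmarked against
  the IBSI digital-phantom reference values; the inventory, determinism,
  invariances and matrix-level brute-force equivalence are what the tests
  establish.
* Synthetic cohorts cannot reproduce clinical accuracy levels; the
  benchmark demonstrates protocol correctness (chance on permuted labels,
  recovery of injected signal), not clinical performance.
* The numpy engine is CPU-oriented and single-threaded-deterministic; it is
  not a general training framework.
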