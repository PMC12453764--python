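# Methods

This note documents the models, the synthetic data, the numerical choices
and the limits of what the test suite shows. It states no number that the
tests or `scripts/acceptance.py` do not themselves compute.

## Preprocessing

Images are cleaned in the order **resample → denoise → skin-mask →
normalize**; augmentation is train-time only.

- **Resampling** is, by default, a pure index remap: output pixel (x, y)
  takes the input value at (⌊x·H/H′⌋, ⌊y·W/W′⌋). It introduces no new
  intensities, which makes it exactly testable; a bilinear mode is available
  when visual quality matters more than exactness.
- **SANLM denoising** replaces each pixel with a similarity-weighted average
  of its search window: `w(p,q) = exp(−D(p,q)/h²)`, where D is the squared
  intensity distance (Euclidean over RGB, weights shared across channels),
  averaged over a patch neighborhood of radius `sanlm_patch_radius`
  (default 1; radius 0 gives the pure pixelwise form). Defaults: search
  radius 2 (5×5 window), `h = 0.1` on [0,1] intensities — standard
  non-local-means practice; both windows truncate at image borders. The
  output is a convex combination of inputs, so its range never leaves the
  input range.
- **Skin masking** thresholds the Rec.601 luma (0.299, 0.587, 0.114) at an
  Otsu threshold computed on the 256-bin 8-bit histogram; the mask keeps
  pixels *above* the threshold and multiplies the image elementwise
  (background → 0). Otsu ties go to the smallest threshold, and for count
  (integer) histograms the argmin is evaluated in exact integer arithmetic
  so floating-point rounding can never flip a near-tie. A constant image has
  no meaningful threshold and raises.
- **Normalization** is min–max to [0,1] with the fit recorded
  (I_min, I_max). A constant image maps to zeros with a `degenerate` flag
  rather than dividing by zero. The operation is idempotent.
- **Rotation** is about the image center (origin rotation would move the
  content off-canvas), nearest-neighbor, with vacated pixels set to 0.
  Brightness multiplies then clips to [0,1].

Note on notation: the skin mask and the disease probability map are both
conventionally written M(x, y); the code uses `SkinMask` and `ProbMap` to
keep them apart.

## Patching

Non-overlapping tiling (stride = patch size) is the default, giving exactly
⌊H/p⌋·⌊W/p⌋ patches; remainder rows/columns that cannot host a full patch
are left uncovered and carry zero coverage and zero map probability.
Overlapping grids (default stride p/2 = 16 for map generation — a
documented package choice) serve the max-aggregation, where a pixel's map
value is the max over all covering patches. Coordinates are 0-based
(row, col), row-major throughout.

## The FCRN patch classifier

Input 32×32×3 in [0,1]. Architecture: 3×3/64 stride-1 convolution →
activation → residual block (two 3×3/64 convolutions with batch-norm, ReLU
inside the block, identity skip, ReLU after the add) → 2×2/2 max-pool →
second residual block → 3×3/128 convolution → activation → global average
pooling → 1×1 convolutional head with one filter per class → softmax. There
are no dense layers on the spatial path, so the network accepts any input
of at least 32×32 without rebuilding. ReLU is used inside residual blocks;
the configurable outer activation defaults to leaky-ReLU (slope 0.01),
the optimum of the tuning grid. "3-D convolution" in some descriptions of
this family of models is read as 2-D convolution over 3-channel input.

**Patch labels.** A patch is diseased iff ≥ 50% of its pixels fall inside
the ground-truth lesion mask; without a mask it inherits its image's label.
Patch datasets are therefore heavily imbalanced (a 64×64 diseased image
contributes at most one majority-lesion patch out of four), and training
uses class-weighted cross-entropy (weights n/(k·n_c), the scikit-learn
"balanced" convention) as the imbalance correction.

**Training.** Adam (lr 0.001), batch 32 for the FCRN and 16 for the fusion
network (both appear in the protocol; each network keeps its own default),
cross-entropy loss, per-epoch train/validation history, best-validation
checkpointing and early stopping (default patience 10). He-uniform
initialization, all seeded. Default arithmetic is float32 for speed;
gradient-check tests build float64 models.

**Batch-norm.** Biased batch statistics during training; running moments
(momentum 0.1) at inference. The running moments are seeded from the first
training batch instead of (0, 1): with short trainings on features whose
scale is far from 1 (region tensors distilled from confident probability
maps can sit at 1e-5), the conventional cold start leaves inference
statistics orders of magnitude off and collapses inference-mode predictions
while training-mode accuracy looks fine. First-batch seeding removes the
transient without changing the converged behaviour.

## Probability maps, regions, and the fusion network

Patch probabilities are broadcast over each patch's footprint and
max-aggregated per pixel; uncovered pixels are 0 with coverage 0. High-risk
regions are disjoint 32×32 windows (stride 32, preventing near-duplicate
top regions), optionally pre-filtered by `M ≥ T` (default T = 0.5), ranked
by mean intensity with (row, col) tie-breaks; the top N (default 8) are
kept. If the threshold filters out everything, the pipeline falls back to
the unfiltered ranking so the fusion input keeps a fixed shape.

Each 32×32 region is reduced to its 32 **column means** to form the
(N, 1, 32) fusion tensor. A literal row-major flattening of a 32×32 region
has length 1024 and cannot fill a width-32 tensor; column means preserve a
1-D spatial profile at the printed width. The full flattening is available
as `mode="flat"`. Missing regions are zero-padded.

The fusion branch convolves each length-32 profile (1-D kernels of size 3,
16 then 32 channels, batch-norm + ReLU — the branch description that
carries complete shapes; a 2-D 64/128-filter branch over a downsampled map
is selectable via `FusionSpec(branch="conv2d")`). Global average pooling
averages over both the N regions and the 32 positions, giving one value per
kernel channel (so the pooled vector has length 32 and the model is
invariant to region order). Clinical features enter only after pooling
(late fusion): `F_fusion = [F_gap, C_f]`, length 32 + dim(C_f). The head is
dense 128 → dense 64 (leaky-ReLU 0.01, dropout 0.1 on both — the tuned
dropout optimum) → 2 logits → softmax. Default fusion training: Adam
lr 0.001, batch 16, 10 epochs.

## Clinical encoding

Continuous fields are z-scored with the **population** σ (divide by n; the
convention is fixed and tested). Categorical fields are one-hot in
lexicographically sorted vocabulary order. Layout is deterministic:
continuous block first (columns alphabetical), then one block per
categorical column. Fitting uses the training table only; transforming an
unseen category raises an error naming the column and value. Missing
continuous values are imputed with the training median; missing categoricals
get an explicit "missing" category (self-reported clinical tables are
sparse). Constant continuous columns (σ = 0) are dropped with a warning.

## Synthetic cohorts

The generator emulates what the pipeline needs from real data: RGB skin
images in which diseased cases carry one axis-aligned elliptical lesion of
shifted mean intensity and rougher texture, pixel-level masks, and clinical
covariates with a controllable association to the label.

Defaults (the package's standing study conditions): 64×64 images,
prevalence 0.5 with deterministic stratified label assignment, skin-tone
background RGB (0.76, 0.57, 0.45) with Gaussian noise σ = 0.05, lesion
semi-axes uniform in (8, 16) px — the lesion occupies roughly 5–20% of the
image, so the majority-coverage patch-label rule is well posed — intensity
shift 0.2 (the midpoint of the 0–0.3 separability ladder the tests sweep),
lesion texture σ = 0.08. Clinical schema: age ~ Normal(50, 15) truncated to
[18, 90]; gender F/M; Fitzpatrick type I–VI with a mixed-cohort frequency
profile; history flag Bernoulli(0.3); symptom duration exponential with
mean 30 d for the healthy class.

**Clinical effect size.** The informative covariate is symptom duration,
exponential with label-conditional rates λ₀, λ₁. The log-likelihood ratio
of two exponentials is linear in x with slope λ₀ − λ₁; evaluating the Bayes
log-odds at the two class-conditional means and differencing gives
(r − 1)²/r with r = λ₀/λ₁. `clinical_effect_beta` is that difference, and
the generator solves for r; β = 0 reproduces identical distributions (the
tested null), β = 3 gives r ≈ 4.79 (diseased mean duration ≈ 144 d).

What the generator does **not** emulate: photographic illumination and
color variation, hair and occlusions, multi-lesion or multi-class disease,
irregular lesion shapes, and correlated clinical covariates. Passing tests
therefore demonstrate that the pipeline recovers planted signal of the
stated kind and size — not clinical performance on real dermatology data.

## Evaluation protocol

Stratified 70/15/15 splits and stratified 5-fold plans use per-class
largest-remainder allocation; tie remainders rotate across classes so
leftovers spread over parts. Both are deterministic per seed, and both a
hold-out split and k-fold CV are available since protocols of this kind
commonly report either. Metrics come from the confusion matrix (undefined
ratios are explicit `None`, never silent 0); AUC is the Mann–Whitney rank
statistic with ties counted ½ (it equals the trapezoidal area under the
swept ROC when there are no ties), invariant under monotone score
transforms. Grid search enumerates the full Cartesian space (the tuning
protocol's crossed grid is 3⁵ = 243 cells), records per-cell failures
without aborting, and breaks metric ties by grid order.

`run_experiment` trains three architecture-matched variants on one shared
split: image-only (the fusion network without the clinical concatenation),
clinical-only (an MLP with 64/32 leaky-ReLU hidden layers — a baseline
shape chosen here, not a claim from elsewhere), and fused. Synthetic
cohorts come out of the generator already standardized, so the experiment
harness consumes them directly; the full preprocessing chain applies when
predicting from raw photographs (`PipelineConfig(apply_preprocess=True)`).
For multi-seed robustness statements the fusion/image-only heads are
retrained under extra seeds over region tensors computed once.

## Problem sizes

The test suite and the acceptance script run scaled-down cohorts chosen as
the package's own desk-scale conditions: 600-image 64×64 cohorts for the
end-to-end recovery checks (FCRN capped at 400 patches per class, 2–4
epochs; map stride 32 in the experiment harness), 450 images in the
acceptance script, and reduced-width but architecturally identical networks
for full finite-difference gradient checks. Gradient agreement is measured
per parameter tensor as ‖g_num − g_ana‖ / max(‖g_num‖ + ‖g_ana‖, 10⁻⁶); the
floor absorbs tensors whose true gradient is identically zero (convolution
biases immediately followed by batch-norm), where both sides are pure
finite-difference noise.

## Known limitations

- The desk-scale synthetic experiments demonstrate mechanism, not clinical
  accuracy; headline numbers from full-scale studies on real cohorts are
  out of reach by design here.
- Max-aggregation makes the map sensitive to a single overconfident patch;
  no smoothing is applied.
- The region tensor's column-mean reduction discards within-column
  structure; `flat` mode keeps it at the cost of a much wider branch input.
- Otsu masking assumes foreground brighter than background; on lesions
  darker than skin the mask logic applies to skin-vs-background, not
  lesion-vs-skin.
- The numpy networks are CPU-only and single-threaded beyond BLAS; they are
  sized for patches, not for large-resolution end-to-end training.
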