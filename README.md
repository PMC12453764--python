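# dermapatch

Patch-based skin-lesion analysis with interpretable disease probability maps
and image + clinical multimodal fusion.

## The problem

Whole-image skin-disease classifiers pool away exactly the local evidence —
lesion borders, pigmentation, texture irregularity — that a dermatologist
looks at, and they ignore the clinical context (age, symptom duration, skin
phototype, history) that shapes a real diagnosis. `dermapatch` implements a
two-stage alternative for binary diseased/healthy classification of RGB skin
photographs:

1. **Patch stage.** Cleaned images are tiled into p×p patches (default
   32×32). A small *fully convolutional residual network* (FCRN) — one
   3×3/64 convolution, two 64-wide residual blocks
   `R(x) = ReLU(BN(W₂·ReLU(BN(W₁·x))) + x)` with a 2×2 max-pool between
   them, a 3×3/128 convolution, global average pooling and a 1×1
   convolutional head with softmax — scores each patch with a diseased
   probability `P(c|x) = exp(z_c) / Σ_j exp(z_j)`. Patch probabilities are
   max-aggregated per pixel into a disease probability map
   `M(x,y) = max_k P_k(x,y)`, an interpretable heat surface over the image.
2. **Fusion stage.** The top-N 32×32 high-risk windows of the map (mean
   intensity ranking, optional threshold `M ≥ T`) are reduced to a region
   tensor of shape (N, 1, 32). A 1-D convolutional branch (16 then 32
   kernels, batch-norm, global average pooling) compresses it to a
   32-vector F_gap, which is concatenated with the encoded clinical vector
   C_f (z-scored continuous fields, one-hot categoricals) and passed through
   dense layers (128 → 64, leaky-ReLU, dropout 0.1) to the final two-class
   softmax.

Preprocessing (index-remap resampling, adaptive non-local-means denoising,
Otsu-threshold skin masking, min–max normalization, rotation/flip/crop/
brightness augmentation), a stratified 70/15/15 + 5-fold evaluation
protocol, confusion-matrix metrics with rank-based AUC, grid search, and a
synthetic cohort generator with ground-truth lesion masks are all part of
the package. The networks are implemented directly in numpy (exact
forward/backward passes, Adam, gradient-checked), so the package has no
deep-learning-framework dependency.

## Worked example

```python
from dermapatch import (SynthConfig, generate_cohort, FcrnSpec,
                        FcrnTrainConfig, train_fcrn, extract_patches,
                        aggregate_map, top_regions)
from dermapatch.fcrn import patch_dataset

cohort = generate_cohort(SynthConfig(
    n_images=80, image_size=(64, 64), lesion_axes_range=(13, 16),
    lesion_intensity_shift=0.3, seed=5))
x, y, _ = patch_dataset(cohort, patch_size=32, stride=16)
model, history = train_fcrn(x, y, FcrnSpec(),
                            FcrnTrainConfig(epochs=3, seed=5, patience=3))

sample = next(s for s in cohort if s.label == 1)
grid = extract_patches(sample.image, 32, 16)
pmap = aggregate_map(grid, model.predict_proba(grid.stack())[:, 1])
mask = sample.lesion_mask.astype(bool)
print(pmap.values[mask].mean(), pmap.values[~mask].mean())
```

This prints `0.969 0.220` (with these seeds): the probability map averages
0.97 inside the true lesion and 0.22 outside — the patch classifier has
localised the lesion without ever seeing a pixel-level label at test time.
The same run reports per-epoch validation accuracies of
`[0.963, 0.917, 0.963]` on held-out patches. The scripts in `examples/`
walk through every capability (cohort simulation, preprocessing and
patching, probability maps, clinical encoding, and the image-only /
clinical-only / fused comparison) with printed, explained output.

A thin CLI wraps the same library calls for shell use:

```bash
dermapatch simulate --n 200 --seed 1 --out cohort/
dermapatch train-fcrn --data cohort/ --out ckpt.npz --seed 1
dermapatch probmap --model ckpt.npz --image cohort/img_00000.png --out maps/
dermapatch evaluate --data cohort/ --seed 1 --out report/
```

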