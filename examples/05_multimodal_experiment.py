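"""Compare image-only, clinical-only and fused classifiers on one cohort.

All three variants share the same stratified 70/15/15 split. The image
branch consumes region tensors distilled from FCRN probability maps; the
clinical branch consumes the encoded covariate vector; the fused model
concatenates both after global average pooling. With both signals
informative the fused model should match or beat each single modality.
"""

from dermapatch import SynthConfig, generate_cohort
from dermapatch.evaluate import run_experiment, ExperimentConfig

cohort = generate_cohort(SynthConfig(
    n_images=200, image_size=(64, 64), lesion_intensity_shift=0.3,
    clinical_effect_beta=2.0, seed=13))

report = run_experiment(cohort, ExperimentConfig(
    seed=13, fcrn_epochs=2, per_class_patches=200, map_stride=32))

pm = report["fcrn_val_patch_metrics"]
print(f"FCRN patch-level validation: accuracy {pm.accuracy:.3f}, AUC {pm.auc}")
print(f"{'variant':>15s} {'val acc':>8s} {'test acc':>9s} {'test AUC':>9s}")
for name, runs in report["variants"].items():
    val, test = runs[0]["val"], runs[0]["test"]
    auc = "n/a" if test.auc is None else f"{test.auc:9.3f}"
    print(f"{name:>15s} {val.accuracy:8.3f} {test.accuracy:9.3f} {auc}")
# accuracies are fractions of the 30-image val / 30-image test splits
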