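"""Experimental protocol: stratified splits, 5-fold CV, grid search, metrics,
and the three-variant (image-only / clinical-only / fused) experiment.

Metrics follow the confusion-matrix definitions (accuracy, sensitivity =
TPR, specificity, precision, F1) with AUC computed as the Mann-Whitney rank
statistic (ties counted 1/2) — the probability a random positive outscores a
random negative. Ratios with zero denominators are reported as explicit
``None`` markers rather than silent zeros.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from dermapatch import nn
from dermapatch.fcrn import (
    FcrnSpec, FcrnTrainConfig, FcrnModel, train_fcrn, patch_dataset,
    balanced_subsample, _fit, _take,
)
from dermapatch.fusion import (
    FusionSpec, FusionTrainConfig, FusionModel, train_fusion,
    PipelineConfig, image_to_region_tensor,
)
from dermapatch.clinical import fit_encoder, transform


# ---------------------------------------------------------------------------
# splits

@dataclasses.dataclass
class SplitPlan:
    train: np.ndarray
    val: np.ndarray
    test: np.ndarray
    seed: int


@dataclasses.dataclass
class FoldPlan:
    folds: list     # k test-index arrays forming a partition
    seed: int


def _allocate(n: int, fractions, rotation: int = 0) -> list[int]:
    """Largest-remainder allocation of n items to the given fractions.

    ``rotation`` rotates the tie-break order among equal remainders so that,
    when several classes are allocated in turn, their leftover samples spread
    across parts instead of piling onto the same one.
    """
    k = len(fractions)
    raw = [n * f for f in fractions]
    counts = [int(np.floor(r)) for r in raw]
    short = n - sum(counts)
    order = sorted(range(k),
                   key=lambda i: (-(raw[i] - np.floor(raw[i])), (i + rotation) % k))
    for j in range(short):
        counts[order[j]] += 1
    return counts


def stratified_split(labels, fractions=(0.70, 0.15, 0.15), seed: int = 0) -> SplitPlan:
    """Stratified train/val/test split by largest-remainder allocation per class.

    Each part's per-class count is within one sample of the exact
    proportional share; parts are disjoint and exhaustive; the same seed
    always yields the same plan.
    """
    labels = np.asarray(labels)
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("stratified split requires at least two classes")
    rng = np.random.default_rng(seed)
    parts = [[], [], []]
    for ci, c in enumerate(classes):
        idx = np.flatnonzero(labels == c)
        rng.shuffle(idx)
        counts = _allocate(len(idx), fractions, rotation=ci)
        if any(ct == 0 for ct, f in zip(counts, fractions) if f > 0):
            raise ValueError(
                f"class {c!r} has only {len(idx)} samples: too few to "
                f"stratify over fractions {fractions}"
            )
        pos = 0
        for part, ct in zip(parts, counts):
            part.extend(idx[pos:pos + ct])
            pos += ct
    return SplitPlan(
        train=np.sort(np.asarray(parts[0])),
        val=np.sort(np.asarray(parts[1])),
        test=np.sort(np.asarray(parts[2])),
        seed=seed,
    )


def kfold(labels, k: int = 5, seed: int = 0) -> FoldPlan:
    """Stratified k-fold partition; every index lands in exactly one test fold."""
    labels = np.asarray(labels)
    n = len(labels)
    if n < k:
        raise ValueError(f"cannot make {k} folds from {n} samples")
    rng = np.random.default_rng(seed)
    folds = [[] for _ in range(k)]
    for ci, c in enumerate(np.unique(labels)):
        idx = np.flatnonzero(labels == c)
        if len(idx) < k:
            raise ValueError(f"class {c!r} has {len(idx)} samples, fewer than k={k}")
        rng.shuffle(idx)
        counts = _allocate(len(idx), [1.0 / k] * k, rotation=ci)
        pos = 0
        for f, ct in zip(folds, counts):
            f.extend(idx[pos:pos + ct])
            pos += ct
    return FoldPlan(folds=[np.sort(np.asarray(f)) for f in folds], seed=seed)


# ---------------------------------------------------------------------------
# metrics

@dataclasses.dataclass
class MetricsReport:
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float | None
    specificity: float | None
    precision: float | None
    f1: float | None
    auc: float | None
    roc_points: list  # (fpr, tpr) pairs swept over score thresholds

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("roc_points")
        return d


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def rank_auc(labels: np.ndarray, scores: np.ndarray) -> float | None:
    """Mann-Whitney AUC: P(score_pos > score_neg) with ties counted 1/2."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=np.float64)
    n1 = int(np.sum(labels == 1))
    n0 = int(np.sum(labels == 0))
    if n1 == 0 or n0 == 0:
        return None
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def roc_points(labels: np.ndarray, scores: np.ndarray) -> list:
    """(FPR, TPR) swept over the unique score thresholds, (0,0) to (1,1)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=np.float64)
    n1 = max(int(np.sum(labels == 1)), 1)
    n0 = max(int(np.sum(labels == 0)), 1)
    pts = [(0.0, 0.0)]
    for t in np.unique(scores)[::-1]:
        pred = scores >= t
        tp = int(np.sum(pred & (labels == 1)))
        fp = int(np.sum(pred & (labels == 0)))
        pts.append((fp / n0, tp / n1))
    if pts[-1] != (1.0, 1.0):
        pts.append((1.0, 1.0))
    return pts


def compute_metrics(labels, predicted, scores=None) -> MetricsReport:
    """Confusion-matrix metrics plus rank AUC and ROC sweep.

    ``scores`` (higher = more diseased) are optional; without them AUC and
    the ROC sweep are skipped.
    """
    labels = np.asarray(labels).astype(int)
    predicted = np.asarray(predicted).astype(int)
    if labels.shape != predicted.shape:
        raise ValueError("labels and predictions must have equal length")
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValueError("labels must be binary (0/1)")
    tp = int(np.sum((predicted == 1) & (labels == 1)))
    fp = int(np.sum((predicted == 1) & (labels == 0)))
    tn = int(np.sum((predicted == 0) & (labels == 0)))
    fn = int(np.sum((predicted == 0) & (labels == 1)))
    n = len(labels)
    sens = _ratio(tp, tp + fn)
    prec = _ratio(tp, tp + fp)
    if sens is None or prec is None or (prec + sens) == 0:
        f1 = None
    else:
        f1 = 2 * prec * sens / (prec + sens)
    return MetricsReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=(tp + tn) / n if n else None,
        sensitivity=sens,
        specificity=_ratio(tn, tn + fp),
        precision=prec,
        f1=f1,
        auc=None if scores is None else rank_auc(labels, scores),
        roc_points=[] if scores is None else roc_points(labels, scores),
    )


# ---------------------------------------------------------------------------
# grid search

def grid_search(space: dict, train_fn, maximize: bool = True):
    """Exhaustive search over the Cartesian product of ``space``.

    ``train_fn(params) -> score`` is called for every combination; failures
    are recorded per cell and the search continues. Returns
    (best_params, table) where ties go to the earliest cell in grid order.
    """
    if not space or any(len(v) == 0 for v in space.values()):
        raise ValueError("grid space must be non-empty")
    keys = list(space.keys())
    rows = []
    best_params, best_score = None, None
    for combo in itertools.product(*(space[k] for k in keys)):
        params = dict(zip(keys, combo))
        row = dict(params)
        try:
            score = float(train_fn(params))
            row["score"], row["error"] = score, None
        except Exception as exc:  # noqa: BLE001 - cell failures are data
            row["score"], row["error"] = None, str(exc)
            rows.append(row)
            continue
        rows.append(row)
        better = (best_score is None
                  or (score > best_score if maximize else score < best_score))
        if better:
            best_params, best_score = params, score
    table = pd.DataFrame(rows)
    if best_params is None:
        raise RuntimeError("every grid cell failed")
    return best_params, table


#: the hyperparameter space of the tuning protocol (fully crossed: 3^5 cells)
TUNING_GRID = {
    "learning_rate": [0.01, 0.001, 0.0005],
    "batch_size": [8, 16, 32],
    "dropout": [0.1, 0.2, 0.3],
    "activation": ["relu", "leaky_relu", "tanh"],
    "patch_size": [16, 32, 64],
}


# ---------------------------------------------------------------------------
# clinical-only baseline

class MlpModel:
    """Two-hidden-layer MLP (64, 32, leaky-ReLU) over the clinical vector."""

    def __init__(self, d_in: int, seed: int = 0, dtype: str = "float64",
                 n_classes: int = 2):
        rng = np.random.default_rng(seed)
        dt = np.dtype(dtype).type
        self.dtype = dt
        self.net = nn.Sequential([
            nn.Dense(d_in, 64, rng, dt), nn.LeakyReLU(0.01),
            nn.Dense(64, 32, rng, dt), nn.LeakyReLU(0.01),
            nn.Dense(32, n_classes, rng, dt),
        ])

    def params(self):
        return self.net.params()

    def logits(self, x, training=False):
        return self.net.forward(np.asarray(x, dtype=self.dtype), training)

    def backward(self, dlogits):
        return self.net.backward(dlogits)

    def predict_proba(self, x, batch_size: int = 1024):
        return nn.softmax(self.logits(x))


# ---------------------------------------------------------------------------
# the three-variant experiment

@dataclasses.dataclass(frozen=True)
class ExperimentConfig:
    seed: int = 0
    patch_size: int = 32
    train_stride: int = 32
    val_stride: int = 16     # overlapping val patches: more lesion-majority tiles
    map_stride: int = 16
    top_n: int = 8
    region_threshold: float | None = 0.5
    per_class_patches: int = 400     # balanced cap on FCRN training patches
    fcrn_epochs: int = 8
    fcrn_batch_size: int = 32
    fusion_epochs: int = 10
    fusion_batch_size: int = 16
    head_seeds: tuple[int, ...] = ()  # extra seeds for fusion/image-only heads


def _variant_metrics(model, x, y) -> MetricsReport:
    probs = model.predict_proba(x)
    scores = probs[:, 1]
    return compute_metrics(y, (scores >= 0.5).astype(int), scores)


def run_experiment(samples: list, config: ExperimentConfig | None = None) -> dict:
    """Train and evaluate image-only, clinical-only, and fused variants.

    All three variants share the same stratified 70/15/15 split and the same
    seeded training protocol, so modality comparisons are like-for-like. The
    image branch input (region tensors) comes from a single FCRN trained on
    lesion-mask-labelled patches of the training images.

    Returns a report dict with per-variant validation/test MetricsReports,
    the FCRN patch-level validation metrics, split indices and histories.
    """
    config = config or ExperimentConfig()
    labels = np.asarray([s.label for s in samples])
    if np.unique(labels).size < 2:
        raise ValueError("experiment cohort must contain both classes")
    split = stratified_split(labels, (0.70, 0.15, 0.15), seed=config.seed)
    tr, va, te = split.train, split.val, split.test

    # --- stage 1: patch-level FCRN ---------------------------------------
    x_tr, y_tr, _ = patch_dataset([samples[i] for i in tr], config.patch_size,
                                  config.train_stride)
    x_va, y_va, _ = patch_dataset([samples[i] for i in va], config.patch_size,
                                  config.val_stride)
    keep = balanced_subsample(y_tr, config.per_class_patches, seed=config.seed)
    fcrn_cfg = FcrnTrainConfig(
        batch_size=config.fcrn_batch_size, epochs=config.fcrn_epochs,
        seed=config.seed, patience=max(3, config.fcrn_epochs),
    )
    fcrn, fcrn_hist = train_fcrn(x_tr[keep], y_tr[keep], FcrnSpec(), fcrn_cfg,
                                 x_val=x_va, y_val=y_va)
    patch_scores = fcrn.predict_proba(x_va)[:, 1]
    fcrn_val = compute_metrics(y_va, (patch_scores >= 0.5).astype(int), patch_scores)

    # --- stage 2: region tensors + clinical vectors for every image ------
    pipe = PipelineConfig(patch_size=config.patch_size, map_stride=config.map_stride,
                          top_n=config.top_n, region_threshold=config.region_threshold)
    tensors = np.stack(
        [image_to_region_tensor(s.image, fcrn, pipe)[0] for s in samples]
    )
    encoder = fit_encoder(pd.DataFrame([samples[i].clinical for i in tr]))
    clin = np.stack([transform(s.clinical, encoder) for s in samples])

    # --- stage 3: the three heads ----------------------------------------
    report = {
        "split": split,
        "fcrn_history": fcrn_hist,
        "fcrn_val_patch_metrics": fcrn_val,
        "variants": {},
        "encoder": encoder,
    }
    head_seeds = (config.seed,) + tuple(config.head_seeds)
    fus_cfg = lambda s: FusionTrainConfig(  # noqa: E731
        batch_size=config.fusion_batch_size, epochs=config.fusion_epochs, seed=s)

    def eval_variant(name, build_and_train):
        runs = []
        for s in head_seeds:
            model, hist = build_and_train(s)
            runs.append({
                "seed": s,
                "val": _variant_metrics(model, _val_x(name), labels[va]),
                "test": _variant_metrics(model, _test_x(name), labels[te]),
                "history": hist,
            })
        report["variants"][name] = runs

    def _val_x(name):
        if name == "clinical_only":
            return clin[va]
        if name == "image_only":
            return tensors[va]
        return (tensors[va], clin[va])

    def _test_x(name):
        if name == "clinical_only":
            return clin[te]
        if name == "image_only":
            return tensors[te]
        return (tensors[te], clin[te])

    try:
        eval_variant("image_only", lambda s: train_fusion(
            tensors[tr], None, labels[tr], FusionSpec(clinical_dim=0),
            fus_cfg(s), val=(tensors[va], labels[va])))
        eval_variant("fused", lambda s: train_fusion(
            tensors[tr], clin[tr], labels[tr], FusionSpec(clinical_dim=clin.shape[1]),
            fus_cfg(s), val=((tensors[va], clin[va]), labels[va])))
        eval_variant("clinical_only", lambda s: _train_mlp(
            clin[tr], labels[tr], clin[va], labels[va], fus_cfg(s)))
    except ValueError as exc:
        raise ValueError(f"variant training failed: {exc}") from exc
    return report


def _train_mlp(x, y, x_val, y_val, config: FusionTrainConfig):
    model = MlpModel(x.shape[1], seed=config.seed)
    rng = np.random.default_rng(config.seed)
    history = _fit(model, x, y, x_val, y_val, config, rng)
    return model, history


def mean_val_accuracy(report: dict, variant: str) -> float:
    """Mean validation accuracy over the head seeds of one variant."""
    runs = report["variants"][variant]
    return float(np.mean([r["val"].accuracy for r in runs]))
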