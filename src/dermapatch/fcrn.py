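"""Patch-level fully convolutional residual network (FCRN).

Architecture, for 32x32x3 RGB patches: a 3x3/64 stride-1 convolution, a
64-wide residual block (two 3x3 convs with batch-norm, ReLU inside the block,
identity skip), 2x2 max-pooling, a second 64-wide residual block, a 3x3/128
convolution, global average pooling to 1x1, and a 1x1 convolutional head with
one filter per class (equivalent, on the pooled 1x1 map, to a 128->C linear
map) followed by softmax. There are no fully connected layers on the spatial
path, so the forward pass accepts any input of at least the patch size.

Training minimises mean cross-entropy with Adam, with per-epoch train and
validation history, best-validation checkpointing and early stopping.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from dermapatch import nn
from dermapatch.synthdata import SynthSample


@dataclasses.dataclass(frozen=True)
class FcrnSpec:
    patch_size: int = 32
    in_channels: int = 3
    conv1_filters: int = 64
    block_filters: int = 64
    conv2_filters: int = 128
    n_classes: int = 2
    activation: str = "leaky_relu"   # activation outside residual blocks
    leaky_alpha: float = 0.01

    def validate(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.activation not in ("relu", "leaky_relu", "tanh"):
            raise ValueError(f"unknown activation {self.activation!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "FcrnSpec":
        return cls(**d)


@dataclasses.dataclass
class PatchPrediction:
    logits: np.ndarray         # length-C
    probabilities: np.ndarray  # length-C, sums to 1


@dataclasses.dataclass(frozen=True)
class FcrnTrainConfig:
    learning_rate: float = 0.001
    batch_size: int = 32
    epochs: int = 100
    seed: int = 0
    patience: int = 10          # early stopping on validation loss
    val_fraction: float = 0.15  # used only when no validation set is passed
    checkpoint_path: str | None = None
    dtype: str = "float32"
    class_weight: str | None = "balanced"  # imbalance correction for patch labels


def _activation(spec: FcrnSpec) -> nn.Layer:
    return {
        "relu": nn.ReLU,
        "leaky_relu": lambda: nn.LeakyReLU(spec.leaky_alpha),
        "tanh": nn.Tanh,
    }[spec.activation]()


def _res_block(width: int, rng, dtype) -> nn.Residual:
    # ReLU(BN(W2 * ReLU(BN(W1 * x))) + x)
    return nn.Residual([
        nn.Conv2D(width, width, 3, rng, dtype),
        nn.BatchNorm(width, dtype=dtype),
        nn.ReLU(),
        nn.Conv2D(width, width, 3, rng, dtype),
        nn.BatchNorm(width, dtype=dtype),
    ])


class FcrnModel:
    """The network plus its spec; callable on NHWC batches of patches."""

    def __init__(self, spec: FcrnSpec, seed: int = 0, dtype: str = "float32"):
        spec.validate()
        self.spec = spec
        self.dtype = np.dtype(dtype).type
        rng = np.random.default_rng(seed)
        dt = self.dtype
        self.net = nn.Sequential([
            nn.Conv2D(spec.in_channels, spec.conv1_filters, 3, rng, dt),
            _activation(spec),
            _res_block(spec.block_filters, rng, dt),
            nn.MaxPool2D(),
            _res_block(spec.block_filters, rng, dt),
            nn.Conv2D(spec.block_filters, spec.conv2_filters, 3, rng, dt),
            _activation(spec),
            nn.GlobalAvgPool2D(),
            nn.Dense(spec.conv2_filters, spec.n_classes, rng, dt),  # 1x1 conv head
        ])

    def logits(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim != 4 or x.shape[3] != self.spec.in_channels:
            raise ValueError(f"expected NHW{self.spec.in_channels} batch, got {x.shape}")
        if x.shape[1] < self.spec.patch_size or x.shape[2] < self.spec.patch_size:
            raise ValueError(
                f"input {x.shape[1]}x{x.shape[2]} smaller than the "
                f"{self.spec.patch_size}-pixel patch size"
            )
        return self.net.forward(x, training)

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Class probabilities for a batch of patches (inference mode)."""
        x = np.asarray(x, dtype=self.dtype)
        out = []
        for i in range(0, len(x), batch_size):
            out.append(nn.softmax(self.logits(x[i:i + batch_size])))
        return np.concatenate(out) if out else np.zeros((0, self.spec.n_classes))

    def params(self):
        return self.net.params()

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        return self.net.backward(dlogits)


def build_fcrn(spec: FcrnSpec | None = None, seed: int = 0, dtype: str = "float32") -> FcrnModel:
    return FcrnModel(spec or FcrnSpec(), seed=seed, dtype=dtype)


def fcrn_forward(patch: np.ndarray, model: FcrnModel) -> PatchPrediction:
    """Score one patch; probabilities are the softmax of the head logits."""
    patch = np.asarray(patch)
    if patch.ndim == 3:
        patch = patch[None]
    if patch.shape[0] != 1:
        raise ValueError("fcrn_forward scores a single patch; use predict_proba for batches")
    z = model.logits(patch)[0]
    return PatchPrediction(logits=z, probabilities=nn.softmax(z[None])[0])


# ---------------------------------------------------------------------------
# patch datasets

def patch_label(mask_patch: np.ndarray) -> int:
    """A patch is diseased iff at least half of its pixels lie in the lesion mask."""
    return int(np.mean(mask_patch) >= 0.5)


def patch_dataset(
    samples: list[SynthSample],
    patch_size: int = 32,
    stride: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Tile a cohort into labelled patches.

    Labels come from the lesion-mask majority rule when a sample has a mask;
    samples without one inherit the image label on every patch. Returns
    (patches, labels, image_index).
    """
    from dermapatch.patching import extract_patches

    xs, ys, idx = [], [], []
    for i, s in enumerate(samples):
        grid = extract_patches(s.image, patch_size, stride)
        mgrid = (extract_patches(s.lesion_mask, patch_size, stride)
                 if s.lesion_mask is not None else None)
        for k, patch in enumerate(grid.patches):
            xs.append(patch.pixels)
            ys.append(patch_label(mgrid.patches[k].pixels)
                      if mgrid is not None else s.label)
            idx.append(i)
    return np.stack(xs), np.asarray(ys, dtype=np.int64), np.asarray(idx, dtype=np.int64)


def balanced_subsample(y: np.ndarray, per_class: int, seed: int = 0) -> np.ndarray:
    """Indices of up to ``per_class`` examples per class, seeded."""
    rng = np.random.default_rng(seed)
    keep = []
    for c in np.unique(y):
        cand = np.flatnonzero(y == c)
        rng.shuffle(cand)
        keep.append(cand[:per_class])
    keep = np.concatenate(keep)
    keep.sort()
    return keep


# ---------------------------------------------------------------------------
# training

def _take(x, idx):
    """Row-select from an array or a tuple of parallel arrays."""
    if isinstance(x, tuple):
        return tuple(a[idx] for a in x)
    return x[idx]


def _n_rows(x) -> int:
    return len(x[0]) if isinstance(x, tuple) else len(x)


def _accuracy(model, x, y: np.ndarray, batch: int = 256):
    probs = model.predict_proba(x, batch)
    loss = -np.mean(np.log(probs[np.arange(len(y)), y] + 1e-12))
    return float(np.mean(probs.argmax(axis=1) == y)), float(loss)


def train_fcrn(
    x: np.ndarray,
    y: np.ndarray,
    spec: FcrnSpec | None = None,
    config: FcrnTrainConfig | None = None,
    x_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
) -> tuple[FcrnModel, dict]:
    """Train the FCRN on labelled patches.

    Returns the model holding the best-validation parameters and a history
    dict with per-epoch train/val loss and accuracy. With ``epochs=0`` the
    returned parameters equal the seeded initialization.
    """
    spec = spec or FcrnSpec()
    config = config or FcrnTrainConfig()
    x = np.asarray(x)
    y = np.asarray(y, dtype=np.int64)
    if len(x) == 0:
        raise ValueError("empty patch dataset")
    if np.unique(y).size < 2 and config.epochs > 0:
        raise ValueError("training requires at least one patch per class")

    rng = np.random.default_rng(config.seed)
    if x_val is None:
        x, y, x_val, y_val = _carve_validation(x, y, config.val_fraction, rng)

    model = FcrnModel(spec, seed=config.seed, dtype=config.dtype)
    history = _fit(model, x, y, x_val, y_val, config, rng)
    if config.checkpoint_path:
        save_checkpoint(model, history, config.checkpoint_path)
    return model, history


def _carve_validation(x, y, frac, rng):
    n_val_per_class = {c: max(1, int(round(np.sum(y == c) * frac))) for c in np.unique(y)}
    val_idx = []
    for c, k in n_val_per_class.items():
        cand = np.flatnonzero(y == c)
        rng.shuffle(cand)
        val_idx.append(cand[:k])
    val_idx = np.concatenate(val_idx)
    mask = np.zeros(len(y), dtype=bool)
    mask[val_idx] = True
    return x[~mask], y[~mask], x[mask], y[mask]


def _class_weights(y: np.ndarray, scheme: str | None) -> np.ndarray | None:
    """'balanced' gives weight n/(k*n_c) per class c, as in scikit-learn."""
    if scheme is None:
        return None
    if scheme != "balanced":
        raise ValueError(f"unknown class_weight scheme {scheme!r}")
    classes, counts = np.unique(y, return_counts=True)
    w = np.ones(int(classes.max()) + 1)
    w[classes] = len(y) / (len(classes) * counts)
    return w


def _fit(model, x, y, x_val, y_val, config, rng) -> dict:
    """Shared mini-batch Adam loop with early stopping; used by both networks."""
    weights = _class_weights(y, getattr(config, "class_weight", None))
    opt = nn.Adam(model.params(), lr=config.learning_rate)
    history = {"train_loss": [], "train_acc": [], "val_loss": [], "val_acc": [],
               "best_epoch": None}
    best_state = nn.get_state(model.net)
    best_val = np.inf
    stale = 0
    n = _n_rows(x)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses, hits = [], 0
        for i in range(0, n, config.batch_size):
            bi = order[i:i + config.batch_size]
            logits = model.logits(_take(x, bi), training=True)
            loss, probs, dlogits = nn.softmax_cross_entropy(logits, y[bi], weights)
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
            hits += int(np.sum(probs.argmax(axis=1) == y[bi]))
        val_acc, val_loss = _accuracy(model, x_val, y_val)
        history["train_loss"].append(float(np.mean(losses)))
        history["train_acc"].append(hits / n)
        history["val_loss"].append(val_loss)
        history["val_acc"].append(val_acc)
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_state = nn.get_state(model.net)
            history["best_epoch"] = epoch
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break
    nn.set_state(model.net, best_state)
    return history


# ---------------------------------------------------------------------------
# checkpoints

def save_checkpoint(model: FcrnModel, history: dict, path: str | Path) -> None:
    """Persist spec + parameters (incl. batch-norm moments) + history."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = nn.get_state(model.net)
    arrays = {f"arr_{i}": a for i, a in enumerate(state)}
    meta = json.dumps({"spec": model.spec.to_dict(), "history": history,
                       "dtype": np.dtype(model.dtype).name})
    np.savez(path, meta=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path) -> tuple[FcrnModel, dict]:
    with np.load(Path(path).with_suffix(".npz") if not str(path).endswith(".npz")
                 else path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        n_arr = len([k for k in data.files if k.startswith("arr_")])
        state = [data[f"arr_{i}"] for i in range(n_arr)]
    model = FcrnModel(FcrnSpec.from_dict(meta["spec"]), dtype=meta["dtype"])
    nn.set_state(model.net, state)
    return model, meta["history"]
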