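"""Multimodal fusion network: region tensor + clinical vector -> diagnosis.

The default 1-D branch convolves each length-32 region profile (16 then 32
kernels of size 3, stride 1, 'same' padding, batch-norm + ReLU), global
average pooling collapses it over both the N regions and the 32 positions to
a length-32 vector F_gap, which is concatenated with the clinical vector C_f
(so the fused vector has length 32 + dim(C_f)) and passed through dense
layers of 128 and 64 neurons (leaky-ReLU, dropout 0.1) to a 2-class softmax.

An alternative 2-D branch (3x3 convolutions with 64 then 128 filters over a
downsampled probability map, GAP to length 128) is selectable via
``FusionSpec(branch="conv2d")``.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from dermapatch import nn
from dermapatch.fcrn import FcrnModel, _fit, _take
from dermapatch.patching import extract_patches
from dermapatch.probmap import aggregate_map, top_regions, regions_to_tensor, ProbMap


@dataclasses.dataclass(frozen=True)
class FusionSpec:
    branch: str = "conv1d"          # "conv1d" (default) or "conv2d"
    clinical_dim: int = 0           # dim(C_f); 0 gives the image-only variant
    conv1d_kernels: tuple[int, int] = (16, 32)
    conv2d_filters: tuple[int, int] = (64, 128)
    conv2d_in_channels: int = 1
    dense_units: tuple[int, int] = (128, 64)
    dropout: float = 0.1
    leaky_alpha: float = 0.01
    n_classes: int = 2

    @property
    def gap_width(self) -> int:
        return self.conv1d_kernels[1] if self.branch == "conv1d" else self.conv2d_filters[1]

    def validate(self) -> None:
        if self.branch not in ("conv1d", "conv2d"):
            raise ValueError(f"unknown branch {self.branch!r}")
        if self.clinical_dim < 0:
            raise ValueError("clinical_dim must be >= 0")


@dataclasses.dataclass
class FusionPrediction:
    logits: np.ndarray
    probabilities: np.ndarray


@dataclasses.dataclass(frozen=True)
class FusionTrainConfig:
    learning_rate: float = 0.001
    batch_size: int = 16
    epochs: int = 10
    seed: int = 0
    patience: int = 10
    val_fraction: float = 0.15
    dtype: str = "float64"


class FusionModel:
    """Convolutional branch + GAP + clinical concatenation + dense head."""

    def __init__(self, spec: FusionSpec, seed: int = 0, dtype: str = "float64"):
        spec.validate()
        self.spec = spec
        self.dtype = np.dtype(dtype).type
        rng = np.random.default_rng(seed)
        dt = self.dtype
        a = spec.leaky_alpha
        if spec.branch == "conv1d":
            k1, k2 = spec.conv1d_kernels
            self.branch = nn.Sequential([
                nn.Conv1D(1, k1, 3, rng, dt), nn.BatchNorm(k1, dtype=dt), nn.ReLU(),
                nn.Conv1D(k1, k2, 3, rng, dt), nn.BatchNorm(k2, dtype=dt), nn.ReLU(),
            ])
        else:
            f1, f2 = spec.conv2d_filters
            self.branch = nn.Sequential([
                nn.Conv2D(spec.conv2d_in_channels, f1, 3, rng, dt),
                nn.BatchNorm(f1, dtype=dt), nn.ReLU(),
                nn.Conv2D(f1, f2, 3, rng, dt), nn.BatchNorm(f2, dtype=dt), nn.ReLU(),
            ])
        d1, d2 = spec.dense_units
        fused = spec.gap_width + spec.clinical_dim
        self.head = nn.Sequential([
            nn.Dense(fused, d1, rng, dt), nn.LeakyReLU(a), nn.Dropout(spec.dropout, seed),
            nn.Dense(d1, d2, rng, dt), nn.LeakyReLU(a), nn.Dropout(spec.dropout, seed + 1),
            nn.Dense(d2, spec.n_classes, rng, dt),
        ])
        # container for parameter/state traversal only; forward goes via logits()
        self.net = nn.Sequential([self.branch, self.head])

    def params(self):
        return self.net.params()

    def reseed_dropout(self, seed: int) -> None:
        for i, layer in enumerate(nn.iter_layers(self.net)):
            if isinstance(layer, nn.Dropout):
                layer.reseed(seed + i)

    # -- forward / backward -------------------------------------------------

    def _split(self, x):
        regions, clinical = x if isinstance(x, tuple) else (x, None)
        regions = np.asarray(regions, dtype=self.dtype)
        if clinical is None:
            clinical = np.zeros((len(regions), 0), dtype=self.dtype)
        clinical = np.asarray(clinical, dtype=self.dtype)
        if clinical.ndim == 1:
            clinical = clinical[None] if len(regions) == 1 else clinical[:, None]
        if clinical.shape[1] != self.spec.clinical_dim:
            raise ValueError(
                f"clinical vector length {clinical.shape[1]} does not match "
                f"the fitted dimension {self.spec.clinical_dim}"
            )
        return regions, clinical

    def logits(self, x, training: bool = False) -> np.ndarray:
        regions, clinical = self._split(x)
        if self.spec.branch == "conv1d":
            if regions.ndim == 3:          # (B, N, 32) -> (B, N, 1, 32)
                regions = regions[:, :, None, :]
            if regions.ndim != 4 or regions.shape[2] != 1:
                raise ValueError(
                    f"region tensor must be (B, N, 1, 32), got {regions.shape}"
                )
            b, n_reg, _, width = regions.shape
            seq = regions.reshape(b * n_reg, width, 1)       # NLC, 1 channel
            feat = self.branch.forward(seq, training)        # (B*N, L, k2)
            self._gap_shape = (b, n_reg * width)
            gap = feat.reshape(b, n_reg * width, -1).mean(axis=1)
        else:
            if regions.ndim != 4:
                raise ValueError(
                    f"conv2d branch expects (B, H', W', C), got {regions.shape}"
                )
            feat = self.branch.forward(regions, training)
            self._gap_shape = (feat.shape[0], feat.shape[1] * feat.shape[2])
            gap = feat.mean(axis=(1, 2))
        fused = np.concatenate([gap, clinical], axis=1)
        self._feat_shape = feat.shape
        return self.head.forward(fused, training)

    def backward(self, dlogits: np.ndarray) -> None:
        dfused = self.head.backward(dlogits)
        dgap = dfused[:, :self.spec.gap_width]
        b, positions = self._gap_shape
        shape = self._feat_shape
        if self.spec.branch == "conv1d":
            dfeat = np.broadcast_to(
                dgap[:, None, :] / positions, (b, positions, dgap.shape[1])
            ).reshape(shape)
        else:
            dfeat = np.broadcast_to(
                dgap[:, None, None, :] / positions, shape
            )
        self.branch.backward(np.ascontiguousarray(dfeat))

    def predict_proba(self, x, batch_size: int = 256) -> np.ndarray:
        n = len(x[0]) if isinstance(x, tuple) else len(x)
        out = []
        for i in range(0, n, batch_size):
            idx = slice(i, i + batch_size)
            out.append(nn.softmax(self.logits(_take(x, np.arange(n)[idx]))))
        return np.concatenate(out) if out else np.zeros((0, self.spec.n_classes))


def build_fusion(spec: FusionSpec | None = None, seed: int = 0,
                 dtype: str = "float64") -> FusionModel:
    return FusionModel(spec or FusionSpec(), seed=seed, dtype=dtype)


def fusion_forward(regions: np.ndarray, clinical: np.ndarray | None,
                   model: FusionModel) -> FusionPrediction:
    """Score one sample: region tensor (N,1,32) + clinical vector (d,)."""
    regions = np.asarray(regions)
    if regions.ndim == 3:
        regions = regions[None]
    clin = None if clinical is None else np.asarray(clinical, dtype=np.float64)[None]
    z = model.logits((regions, clin) if clin is not None else regions)[0]
    return FusionPrediction(logits=z, probabilities=nn.softmax(z[None])[0])


def train_fusion(
    regions: np.ndarray,
    clinical: np.ndarray | None,
    y: np.ndarray,
    spec: FusionSpec | None = None,
    config: FusionTrainConfig | None = None,
    val: tuple | None = None,
) -> tuple[FusionModel, dict]:
    """Train the fusion network on (RegionTensor, ClinicalVector, label) triples.

    ``val`` may supply ((regions, clinical), labels); otherwise a stratified
    fraction is carved from the training data. ``epochs=0`` returns the
    seeded initialization untouched.
    """
    regions = np.asarray(regions)
    y = np.asarray(y, dtype=np.int64)
    if len(regions) == 0:
        raise ValueError("empty fusion dataset")
    if np.unique(y).size < 2 and (config is None or config.epochs > 0):
        raise ValueError("training requires both classes present")
    config = config or FusionTrainConfig()
    if clinical is None:
        clinical = np.zeros((len(regions), 0))
    clinical = np.asarray(clinical, dtype=np.float64)
    if spec is None:
        spec = FusionSpec(clinical_dim=clinical.shape[1])

    x = (regions, clinical)
    rng = np.random.default_rng(config.seed)
    if val is None:
        from dermapatch.fcrn import _carve_validation
        # carve on an index array so both inputs stay aligned
        idx = np.arange(len(y))
        tr_idx, _, va_idx, _ = _carve_validation(idx, y, config.val_fraction, rng)
        x_val, y_val = _take(x, va_idx), y[va_idx]
        x, y = _take(x, tr_idx), y[tr_idx]
    else:
        x_val, y_val = val

    model = FusionModel(spec, seed=config.seed, dtype=config.dtype)
    model.reseed_dropout(config.seed)
    history = _fit(model, x, y, x_val, y_val, config, rng)
    return model, history


# ---------------------------------------------------------------------------
# end-to-end prediction

@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    patch_size: int = 32
    map_stride: int = 16          # p/2 by default for map generation
    top_n: int = 8
    region_threshold: float | None = 0.5
    reduction: str = "column_mean"
    apply_preprocess: bool = False
    preprocess: object = None     # PreprocessConfig when apply_preprocess


def image_to_region_tensor(image: np.ndarray, fcrn: FcrnModel,
                           config: PipelineConfig) -> tuple[np.ndarray, ProbMap]:
    """Run preprocess -> patches -> FCRN -> map -> top regions -> tensor."""
    img = image
    if config.apply_preprocess:
        from dermapatch.preprocess import preprocess_image
        img = preprocess_image(img, config.preprocess).pixels
    try:
        grid = extract_patches(img, config.patch_size, config.map_stride)
    except ValueError as exc:
        raise ValueError(f"patching stage failed: {exc}") from exc
    probs = fcrn.predict_proba(grid.stack())[:, 1]
    pmap = aggregate_map(grid, probs)
    regions = top_regions(pmap, config.top_n, config.region_threshold)
    if not regions:
        # nothing passed the threshold: fall back to the best windows so the
        # fusion input shape stays fixed
        regions = top_regions(pmap, config.top_n, None)
    tensor = regions_to_tensor(regions, n_regions=config.top_n, mode=config.reduction)
    return tensor, pmap


def predict_image(
    image: np.ndarray,
    fcrn: FcrnModel,
    fusion: FusionModel,
    encoder,
    clinical_record=None,
    config: PipelineConfig | None = None,
) -> tuple[FusionPrediction, ProbMap]:
    """Full pipeline for one image + clinical record.

    Deterministic given fixed artifacts: every stage runs in inference mode.
    Stage failures propagate with the stage named in the message.
    """
    config = config or PipelineConfig()
    tensor, pmap = image_to_region_tensor(image, fcrn, config)
    clin = None
    if encoder is not None and clinical_record is not None:
        from dermapatch.clinical import transform
        clin = transform(clinical_record, encoder)
    try:
        pred = fusion_forward(tensor, clin, fusion)
    except ValueError as exc:
        raise ValueError(f"fusion stage failed: {exc}") from exc
    return pred, pmap
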