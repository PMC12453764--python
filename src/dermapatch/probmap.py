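"""Disease probability maps and high-risk region extraction.

Patch-level diseased probabilities are broadcast over each patch's footprint
and max-aggregated per pixel into a map M(x, y) in [0, 1]; pixels no patch
covers stay at 0. High-risk regions are disjoint 32x32 windows ranked by
mean map intensity (optionally pre-filtered by a probability threshold T),
and the top-N regions are reduced to the (N, 1, 32) tensor the fusion
network consumes.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from PIL import Image

from dermapatch.patching import PatchGrid, patch_coverage

REGION_SIZE = 32


@dataclasses.dataclass
class ProbMap:
    values: np.ndarray     # H x W in [0,1]
    coverage: np.ndarray   # H x W patch counts
    stride: int


@dataclasses.dataclass
class RiskRegion:
    origin: tuple[int, int]
    values: np.ndarray     # 32 x 32 sub-map
    mean_intensity: float


def aggregate_map(grid: PatchGrid, predictions: np.ndarray) -> ProbMap:
    """Per-pixel max over the diseased probabilities of all covering patches.

    ``predictions`` holds one scalar diseased-class probability per patch, in
    grid order; each is broadcast over its patch footprint before the max.
    """
    predictions = np.asarray(predictions, dtype=np.float64)
    if predictions.ndim != 1 or len(predictions) != grid.count:
        raise ValueError(
            f"need one prediction per patch: got {predictions.shape} "
            f"for {grid.count} patches"
        )
    if predictions.size and (predictions.min() < 0 or predictions.max() > 1):
        raise ValueError("patch probabilities must lie in [0, 1]")
    h, w = grid.source_shape
    p = grid.patch_size
    values = np.zeros((h, w))
    for patch, prob in zip(grid.patches, predictions):
        i, j = patch.origin
        region = values[i:i + p, j:j + p]
        np.maximum(region, prob, out=region)
    return ProbMap(values=values, coverage=patch_coverage(grid), stride=grid.stride)


def threshold_regions(pmap: ProbMap, threshold: float) -> np.ndarray:
    """Boolean mask of the high-risk pixel set {(x,y) : M(x,y) >= T}."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    return pmap.values >= threshold


def top_regions(pmap: ProbMap, n: int, threshold: float | None = None) -> list[RiskRegion]:
    """The N disjoint 32x32 windows with the highest mean map intensity.

    Windows tile the map at stride 32; when a ``threshold`` is given, only
    windows whose mean is >= T survive the ranking. Ties are broken by
    (row, col) ascending, so the result is deterministic and independent of
    enumeration order. Returns min(N, available) regions sorted by mean
    descending.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    h, w = pmap.values.shape
    if h < REGION_SIZE or w < REGION_SIZE:
        raise ValueError(f"map {h}x{w} smaller than the {REGION_SIZE}-pixel window")
    windows = []
    for i in range(0, h - REGION_SIZE + 1, REGION_SIZE):
        for j in range(0, w - REGION_SIZE + 1, REGION_SIZE):
            sub = pmap.values[i:i + REGION_SIZE, j:j + REGION_SIZE]
            windows.append(((i, j), float(sub.mean())))
    if threshold is not None:
        windows = [wd for wd in windows if wd[1] >= threshold]
    windows.sort(key=lambda wd: (-wd[1], wd[0]))
    return [
        RiskRegion(
            origin=org,
            values=pmap.values[org[0]:org[0] + REGION_SIZE,
                               org[1]:org[1] + REGION_SIZE].copy(),
            mean_intensity=mean,
        )
        for org, mean in windows[:n]
    ]


def regions_to_tensor(regions: list[RiskRegion], n_regions: int | None = None,
                      mode: str = "column_mean") -> np.ndarray:
    """Reduce risk regions to the fusion input tensor of shape (N, 1, 32).

    ``column_mean`` (default) collapses each 32x32 region to its 32 column
    means, preserving a 1-D spatial profile at the printed tensor width;
    ``flat`` keeps the full row-major flattening (rows of length 1024).
    Missing regions (fewer than ``n_regions``) are zero-padded.
    """
    if not regions:
        raise ValueError("empty region list")
    if mode == "column_mean":
        rows = [r.values.mean(axis=0) for r in regions]
    elif mode == "flat":
        rows = [r.values.reshape(-1) for r in regions]
    else:
        raise ValueError(f"unknown reduction mode {mode!r}")
    width = rows[0].shape[0]
    n = n_regions if n_regions is not None else len(rows)
    tensor = np.zeros((n, 1, width))
    for i, row in enumerate(rows[:n]):
        tensor[i, 0, :] = row
    return tensor


# heat colour for overlays: red channel carries the risk
_HEAT_RGB = np.array([1.0, 0.1, 0.1])


def render_overlay(pmap: ProbMap, image: np.ndarray, path=None, alpha: float = 0.5) -> np.ndarray:
    """Alpha-blend the probability map over the image as a heat overlay.

    Pure visualization: blend = (1 - a*M) * image + a*M * heat_colour, so a
    zero map returns the image unchanged and a saturated map shows the full
    heat colour at the set alpha. Optionally writes a PNG to ``path``.
    """
    img = np.asarray(image.pixels if hasattr(image, "pixels") else image, dtype=np.float64)
    if img.shape[:2] != pmap.values.shape:
        raise ValueError(
            f"map {pmap.values.shape} does not match image {img.shape[:2]}"
        )
    if img.ndim == 2:
        img = np.repeat(img[..., None], 3, axis=2)
    weight = (alpha * pmap.values)[..., None]
    overlay = (1.0 - weight) * img + weight * _HEAT_RGB[None, None, :]
    if path is not None:
        arr8 = np.round(np.clip(overlay, 0, 1) * 255).astype(np.uint8)
        Image.fromarray(arr8, mode="RGB").save(path)
    return overlay
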