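"""Tiling images into p x p patches with recorded origins.

With stride s = p the tiling is the non-overlapping grid of
floor(H/p) * floor(W/p) patches; a smaller stride yields overlapping
patches for probability-map aggregation. Remainder rows/columns that
cannot host a full patch are left uncovered (and carry zero coverage).
"""

from __future__ import annotations

import dataclasses

import numpy as np


@dataclasses.dataclass
class Patch:
    pixels: np.ndarray          # p x p (x C) view-copy of the source
    origin: tuple[int, int]     # 0-based (row, col) of the top-left pixel
    index: int                  # 0-based row-major index in the grid


@dataclasses.dataclass
class PatchGrid:
    patches: list[Patch]
    patch_size: int
    stride: int
    source_shape: tuple[int, int]   # (H, W) of the tiled image

    @property
    def count(self) -> int:
        return len(self.patches)

    def origins(self) -> list[tuple[int, int]]:
        return [p.origin for p in self.patches]

    def stack(self) -> np.ndarray:
        """All patch pixels as one array of shape (N, p, p, ...)."""
        return np.stack([p.pixels for p in self.patches])


def extract_patches(image: np.ndarray, patch_size: int, stride: int | None = None) -> PatchGrid:
    """Extract p x p patches at the given stride (default: non-overlapping).

    Origins are every (a*s, b*s) with a*s + p <= H and b*s + p <= W, ordered
    row-major. Each patch's pixels equal the source sub-array exactly.
    """
    arr = np.asarray(image)
    if hasattr(image, "pixels"):          # accept CleanImage transparently
        arr = np.asarray(image.pixels)
    h, w = arr.shape[:2]
    p = int(patch_size)
    s = p if stride is None else int(stride)
    if p < 1 or s < 1:
        raise ValueError(f"patch size and stride must be >= 1, got p={p}, s={s}")
    if p > h or p > w:
        raise ValueError(f"patch size {p} exceeds image dimensions {h}x{w}")

    patches = []
    k = 0
    for i in range(0, h - p + 1, s):
        for j in range(0, w - p + 1, s):
            patches.append(Patch(pixels=arr[i:i + p, j:j + p].copy(), origin=(i, j), index=k))
            k += 1
    return PatchGrid(patches=patches, patch_size=p, stride=s, source_shape=(h, w))


def patch_coverage(grid: PatchGrid) -> np.ndarray:
    """Per-pixel count of patches containing each pixel (0 = uncovered)."""
    h, w = grid.source_shape
    p = grid.patch_size
    cover = np.zeros((h, w), dtype=np.int64)
    for patch in grid.patches:
        i, j = patch.origin
        cover[i:i + p, j:j + p] += 1
    return cover


def stitch(grid: PatchGrid) -> np.ndarray:
    """Reassemble the covered region from a non-overlapping grid.

    Only valid when stride == patch_size; overlapping grids have no unique
    reassembly. Uncovered remainder pixels are returned as zeros.
    """
    if grid.stride != grid.patch_size:
        raise ValueError("stitch requires a non-overlapping grid (stride == patch size)")
    sample = grid.patches[0].pixels
    shape = grid.source_shape + sample.shape[2:]
    out = np.zeros(shape, dtype=sample.dtype)
    p = grid.patch_size
    for patch in grid.patches:
        i, j = patch.origin
        out[i:i + p, j:j + p] = patch.pixels
    return out
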