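"""Image standardisation: resampling, SANLM denoising, Otsu skin masking,
min-max normalization, and train-time augmentation.

The cleaning pipeline runs, in order: resample -> denoise -> skin mask ->
normalize; geometric/photometric augmentation is applied only at train time.
All operations are deterministic.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.ndimage import correlate

#: Rec.601 luma weights used to collapse RGB to intensity for thresholding.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


@dataclasses.dataclass(frozen=True)
class PreprocessConfig:
    target_size: tuple[int, int] = (256, 256)
    sanlm_h: float = 0.1                 # smoothing strength on [0,1] intensities
    sanlm_patch_radius: int = 1          # 0 = pixelwise similarity
    sanlm_search_radius: int = 2         # (2r+1)^2 search window
    resample_mode: str = "nearest"       # "nearest" (index remap) or "bilinear"
    luma_weights: tuple[float, float, float] = LUMA_WEIGHTS
    normalize_epsilon: float = 0.0

    def validate(self) -> None:
        h, w = self.target_size
        if h < 1 or w < 1:
            raise ValueError(f"target_size must be >= (1,1), got {self.target_size}")
        if self.sanlm_h <= 0:
            raise ValueError(f"sanlm_h must be > 0, got {self.sanlm_h}")
        if self.sanlm_search_radius < 1 or self.sanlm_patch_radius < 0:
            raise ValueError("bad SANLM window radii")
        if self.resample_mode not in ("nearest", "bilinear"):
            raise ValueError(f"unknown resample_mode {self.resample_mode!r}")


@dataclasses.dataclass
class SkinMask:
    """Binary foreground mask and the Otsu threshold that produced it."""

    mask: np.ndarray       # H x W, uint8 in {0,1}
    threshold: float       # on the image's intensity scale ([0,1] images)
    threshold_bin: int     # discrete 8-bit level the threshold came from

    def apply(self, image: np.ndarray) -> np.ndarray:
        """Element-wise product I * M; zeroes every background pixel."""
        if image.shape[:2] != self.mask.shape:
            raise ValueError(
                f"mask shape {self.mask.shape} does not match image {image.shape[:2]}"
            )
        m = self.mask if image.ndim == 2 else self.mask[..., None]
        return image * m


@dataclasses.dataclass
class CleanImage:
    """A fully preprocessed image with normalization state and provenance."""

    pixels: np.ndarray     # H' x W' x 3 floats in [0,1]
    i_min: float
    i_max: float
    degenerate: bool = False
    steps: tuple[str, ...] = ()


def resample(image: np.ndarray, target: tuple[int, int], mode: str = "nearest") -> np.ndarray:
    """Resize to ``target`` (rows, cols).

    The default ``nearest`` mode is a pure index remap: output pixel (x, y)
    is the input pixel at (floor(x*H/H'), floor(y*W/W')), so output values
    are a subset of input values. ``bilinear`` interpolates instead.
    """
    th, tw = int(target[0]), int(target[1])
    if th < 1 or tw < 1:
        raise ValueError(f"target dimensions must be positive, got {target}")
    image = np.asarray(image)
    h, w = image.shape[:2]
    if mode == "nearest":
        rows = (np.arange(th) * h) // th
        cols = (np.arange(tw) * w) // tw
        return image[np.ix_(rows, cols)] if image.ndim == 2 else image[np.ix_(rows, cols)]
    if mode == "bilinear":
        from skimage.transform import resize as _resize

        out_shape = (th, tw) if image.ndim == 2 else (th, tw, image.shape[2])
        return _resize(image, out_shape, order=1, mode="edge", anti_aliasing=False,
                       preserve_range=True)
    raise ValueError(f"unknown resample mode {mode!r}")


def _box_sum(arr: np.ndarray, radius: int) -> np.ndarray:
    """Sum over a (2r+1)^2 neighborhood, zero-padded (truncated at borders)."""
    k = np.ones((2 * radius + 1, 2 * radius + 1))
    return correlate(arr, k, mode="constant", cval=0.0)


def sanlm_denoise(image: np.ndarray, config: PreprocessConfig | None = None) -> np.ndarray:
    """Adaptive non-local-means denoising.

    Every output pixel is the similarity-weighted average of the pixels q in
    its search window N_p:

        I_d(p) = sum_q w(p,q) I(q) / sum_q w(p,q),
        w(p,q) = exp(-D(p,q) / h^2)

    where D is the squared intensity distance ||I(p)-I(q)||^2 (Euclidean over
    channels), averaged over a (2*patch_radius+1)^2 patch neighborhood when
    ``sanlm_patch_radius`` > 0. Window and patch are truncated at image
    borders. The output is a convex combination of input pixels, so its range
    never exceeds the input range.
    """
    config = config or PreprocessConfig()
    config.validate()
    img = np.asarray(image, dtype=np.float64)
    single = img.ndim == 2
    if single:
        img = img[..., None]
    h2 = config.sanlm_h ** 2
    R, r = config.sanlm_search_radius, config.sanlm_patch_radius
    H, W, C = img.shape

    num = np.zeros_like(img)
    den = np.zeros((H, W))
    ones = np.ones((H, W))
    for dy in range(-R, R + 1):
        for dx in range(-R, R + 1):
            # shifted[m] = I(m + offset); valid where m + offset is in bounds
            shifted = np.zeros_like(img)
            valid = np.zeros((H, W))
            ys0, ys1 = max(0, -dy), min(H, H - dy)
            xs0, xs1 = max(0, -dx), min(W, W - dx)
            if ys0 >= ys1 or xs0 >= xs1:
                continue
            shifted[ys0:ys1, xs0:xs1] = img[ys0 + dy:ys1 + dy, xs0 + dx:xs1 + dx]
            valid[ys0:ys1, xs0:xs1] = 1.0

            sq = np.sum((img - shifted) ** 2, axis=-1) * valid
            if r > 0:
                d = np.where(valid > 0, _box_sum(sq, r) /
                             np.maximum(_box_sum(valid, r), 1e-300), 0.0)
            else:
                d = sq
            w = np.exp(-d / h2) * valid
            num += w[..., None] * shifted
            den += w
    out = num / den[..., None]
    return out[..., 0] if single else out


def otsu_threshold(histogram: np.ndarray) -> int:
    """Otsu's threshold over a 256-bin intensity histogram.

    Scans every candidate split t (class 0 = bins <= t, class 1 = bins > t)
    and returns the t minimizing the count-weighted within-class variance;
    ties go to the smallest t. Raises on a histogram whose mass sits in a
    single bin, where no split separates anything.
    """
    hist = np.asarray(histogram, dtype=np.float64)
    if hist.ndim != 1 or hist.size != 256:
        raise ValueError(f"expected a 256-bin histogram, got shape {hist.shape}")
    if np.any(hist < 0):
        raise ValueError("histogram counts must be non-negative")
    if np.count_nonzero(hist) < 2:
        raise ValueError("degenerate histogram: all mass in a single bin")

    # Minimising within-class variance == maximising
    # q(t) = m0^2/w0 + m1^2/w1 (total second moment is split-independent).
    # Count histograms are integral, so q is compared in exact integer
    # arithmetic (cross-multiplication) and near-ties cannot be flipped by
    # rounding; non-integral histograms use float64.
    exact = bool(np.all(hist == np.floor(hist)))
    if exact:
        h = [int(v) for v in hist]
        total_w = sum(h)
        total_m = sum(c * l for c, l in zip(h, range(256)))
        best_t, best_num, best_den = None, -1, 1
        w0 = m0 = 0
        for t in range(255):
            w0 += h[t]
            m0 += h[t] * t
            w1 = total_w - w0
            if w0 == 0 or w1 == 0:
                continue
            m1 = total_m - m0
            num = m0 * m0 * w1 + m1 * m1 * w0     # q(t) = num / (w0*w1)
            den = w0 * w1
            if best_t is None or num * best_den > best_num * den:
                best_t, best_num, best_den = t, num, den
        return best_t
    levels = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(hist)[:255]
    m0 = np.cumsum(hist * levels)[:255]
    w1 = hist.sum() - w0
    m1 = (hist * levels).sum() - m0
    ok = (w0 > 0) & (w1 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.where(ok, m0 ** 2 / np.where(w0 > 0, w0, 1)
                     + m1 ** 2 / np.where(w1 > 0, w1, 1), -np.inf)
    return int(np.argmax(q))


def _to_gray_levels(image: np.ndarray, luma=LUMA_WEIGHTS) -> np.ndarray:
    """Discrete 8-bit intensity levels used for both Otsu and masking."""
    img = np.asarray(image, dtype=np.float64)
    gray = img if img.ndim == 2 else img @ np.asarray(luma)
    return np.clip(np.floor(gray * 255.0), 0, 255).astype(np.int64)


def skin_mask(image: np.ndarray, threshold: float | None = None,
              config: PreprocessConfig | None = None) -> SkinMask:
    """Threshold-based foreground (skin) mask: M = 1 where intensity > T.

    ``T`` comes from Otsu's method on the 8-bit luma histogram unless an
    explicit ``threshold`` (on the [0,1] scale) is supplied.
    """
    config = config or PreprocessConfig()
    levels = _to_gray_levels(image, config.luma_weights)
    if threshold is not None:
        t_bin = int(np.floor(threshold * 255.0))
        t_val = float(threshold)
    else:
        hist = np.bincount(levels.ravel(), minlength=256)[:256]
        try:
            t_bin = otsu_threshold(hist)
        except ValueError as exc:
            raise ValueError(f"cannot build skin mask: {exc}") from exc
        t_val = t_bin / 255.0
    mask = (levels > t_bin).astype(np.uint8)
    return SkinMask(mask=mask, threshold=t_val, threshold_bin=t_bin)


def minmax_normalize(image: np.ndarray) -> CleanImage:
    """Linear rescale to [0,1]: I_n = (I - I_min) / (I_max - I_min).

    A constant image cannot be rescaled; it maps to all zeros with the
    ``degenerate`` flag set rather than dividing by zero.
    """
    img = np.asarray(image, dtype=np.float64)
    i_min, i_max = float(img.min()), float(img.max())
    if i_max == i_min:
        return CleanImage(pixels=np.zeros_like(img), i_min=i_min, i_max=i_max,
                          degenerate=True, steps=("normalize",))
    out = (img - i_min) / (i_max - i_min)
    return CleanImage(pixels=out, i_min=i_min, i_max=i_max, steps=("normalize",))


def _rotate_nearest(img: np.ndarray, theta_deg: float) -> np.ndarray:
    """Rotate about the image center, nearest-neighbor, out-of-bounds -> 0."""
    h, w = img.shape[:2]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    th = np.deg2rad(theta_deg)
    c, s = np.cos(th), np.sin(th)
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - cy, xx - cx
    # inverse map: rotate output coords by -theta to find the source pixel
    sy = np.rint(c * dy + s * dx + cy).astype(np.int64)
    sx = np.rint(-s * dy + c * dx + cx).astype(np.int64)
    inb = (sy >= 0) & (sy < h) & (sx >= 0) & (sx < w)
    out = np.zeros_like(img)
    out[inb] = img[sy[inb], sx[inb]]
    return out


def augment(image: np.ndarray | CleanImage, op: str, **params) -> np.ndarray:
    """Apply one augmentation: rotate, hflip, vflip, crop or brightness.

    rotate(theta): nearest-neighbor rotation about the center, vacated
    pixels 0. brightness(s): multiply by s > 0 then clip to [0,1].
    crop(top, left, height, width): sub-window, must lie inside the image.
    """
    img = image.pixels if isinstance(image, CleanImage) else np.asarray(image)
    if op == "rotate":
        return _rotate_nearest(img, float(params["theta"]))
    if op == "hflip":
        return img[:, ::-1].copy()
    if op == "vflip":
        return img[::-1, :].copy()
    if op == "crop":
        top, left = int(params["top"]), int(params["left"])
        ch, cw = int(params["height"]), int(params["width"])
        h, w = img.shape[:2]
        if top < 0 or left < 0 or ch < 1 or cw < 1 or top + ch > h or left + cw > w:
            raise ValueError(
                f"crop window (top={top}, left={left}, {ch}x{cw}) "
                f"outside {h}x{w} image"
            )
        return img[top:top + ch, left:left + cw].copy()
    if op == "brightness":
        s = float(params["s"])
        if s <= 0:
            raise ValueError(f"brightness factor must be > 0, got {s}")
        return np.clip(img * s, 0.0, 1.0)
    raise ValueError(f"unknown augmentation op {op!r}")


def preprocess_image(image: np.ndarray, config: PreprocessConfig | None = None) -> CleanImage:
    """Full cleaning pipeline: resample -> SANLM denoise -> skin mask -> normalize."""
    config = config or PreprocessConfig()
    config.validate()
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 image, got shape {img.shape}")
    if not np.all(np.isfinite(img)) or img.min() < 0:
        raise ValueError("image must contain finite, non-negative values")

    img = resample(img, config.target_size, mode=config.resample_mode)
    img = sanlm_denoise(img, config)
    mask = skin_mask(img, config=config)
    img = mask.apply(img)
    clean = minmax_normalize(img)
    clean.steps = ("resample", "denoise", "mask", "normalize")
    return clean
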