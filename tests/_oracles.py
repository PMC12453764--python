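"""Brute-force reference implementations used as independent test oracles.

Everything here is written as literal loops over definitions, deliberately
independent of the vectorised library code it checks.
"""

import numpy as np


def nlm_reference(image: np.ndarray, h: float, search_radius: int,
                  patch_radius: int) -> np.ndarray:
    """Double-loop non-local-means: for every pixel p, weight every q in the
    search window by exp(-D(p,q)/h^2), D = patch-mean squared intensity
    difference (patches truncated at borders)."""
    img = np.asarray(image, dtype=np.float64)
    single = img.ndim == 2
    if single:
        img = img[..., None]
    H, W, C = img.shape
    out = np.zeros_like(img)
    for py in range(H):
        for px in range(W):
            num = np.zeros(C)
            den = 0.0
            for qy in range(py - search_radius, py + search_radius + 1):
                for qx in range(px - search_radius, px + search_radius + 1):
                    if not (0 <= qy < H and 0 <= qx < W):
                        continue
                    sq_sum, count = 0.0, 0
                    for dy in range(-patch_radius, patch_radius + 1):
                        for dx in range(-patch_radius, patch_radius + 1):
                            ay, ax = py + dy, px + dx
                            by, bx = qy + dy, qx + dx
                            if 0 <= ay < H and 0 <= ax < W and 0 <= by < H and 0 <= bx < W:
                                diff = img[ay, ax] - img[by, bx]
                                sq_sum += float(np.dot(diff, diff))
                                count += 1
                    d = sq_sum / count if count else 0.0
                    w = np.exp(-d / h ** 2)
                    num += w * img[qy, qx]
                    den += w
            out[py, px] = num / den
    return out[..., 0] if single else out


def otsu_exhaustive(hist) -> int:
    """Scan all 255 split points, minimising count-weighted within-class
    variance in exact rational arithmetic; smallest split wins ties."""
    from fractions import Fraction

    h = [Fraction(int(v)) if float(v).is_integer() else Fraction(float(v))
         for v in hist]
    total_w = sum(h)
    total_m = sum(c * l for c, l in zip(h, range(256)))
    total_s = sum(c * l * l for c, l in zip(h, range(256)))
    best_t, best_v = None, None
    w0 = m0 = s0 = Fraction(0)
    for t in range(255):
        w0 += h[t]
        m0 += h[t] * t
        s0 += h[t] * t * t
        w1 = total_w - w0
        if w0 == 0 or w1 == 0:
            continue
        m1, s1 = total_m - m0, total_s - s0
        v = (s0 - m0 * m0 / w0) + (s1 - m1 * m1 / w1)  # within-class SS
        if best_v is None or v < best_v:
            best_v, best_t = v, t
    return best_t


def map_bruteforce(shape, origins, patch_size, probs) -> np.ndarray:
    """Per-pixel max over all patches containing the pixel; 0 if uncovered."""
    H, W = shape
    out = np.zeros((H, W))
    for y in range(H):
        for x in range(W):
            best = 0.0
            covered = False
            for (oy, ox), p in zip(origins, probs):
                if oy <= y < oy + patch_size and ox <= x < ox + patch_size:
                    covered = True
                    best = max(best, p)
            out[y, x] = best if covered else 0.0
    return out


def auc_pairwise(labels, scores) -> float:
    """AUC as the fraction of positive-negative pairs ranked correctly,
    ties counted one half."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=np.float64)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total, wins = 0, 0.0
    for p in pos:
        for q in neg:
            total += 1
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / total


def metrics_bruteforce(labels, predicted) -> dict:
    labels = list(labels)
    predicted = list(predicted)
    tp = sum(1 for l, p in zip(labels, predicted) if l == 1 and p == 1)
    fp = sum(1 for l, p in zip(labels, predicted) if l == 0 and p == 1)
    tn = sum(1 for l, p in zip(labels, predicted) if l == 0 and p == 0)
    fn = sum(1 for l, p in zip(labels, predicted) if l == 1 and p == 0)
    out = {"tp": tp, "fp": fp, "tn": tn, "fn": fn,
           "accuracy": (tp + tn) / len(labels)}
    out["sensitivity"] = tp / (tp + fn) if tp + fn else None
    out["specificity"] = tn / (tn + fp) if tn + fp else None
    out["precision"] = tp / (tp + fp) if tp + fp else None
    if out["precision"] is None or out["sensitivity"] is None or \
            (out["precision"] + out["sensitivity"]) == 0:
        out["f1"] = None
    else:
        out["f1"] = (2 * out["precision"] * out["sensitivity"]
                     / (out["precision"] + out["sensitivity"]))
    return out


def conv2d_reference(x, W, b):
    """Direct-summation stride-1 'same' NHWC convolution."""
    n, H, Wd, cin = x.shape
    kh, kw, _, cout = W.shape
    ph, pw = kh // 2, kw // 2
    out = np.zeros((n, H, Wd, cout))
    for im in range(n):
        for y in range(H):
            for xq in range(Wd):
                for co in range(cout):
                    acc = b[co]
                    for dy in range(kh):
                        for dx in range(kw):
                            sy, sx = y + dy - ph, xq + dx - pw
                            if 0 <= sy < H and 0 <= sx < Wd:
                                acc += float(np.dot(x[im, sy, sx], W[dy, dx, :, co]))
                    out[im, y, xq, co] = acc
    return out


def grad_check(model, x, y, tol=1e-4, floor=1e-6):
    """Numeric-vs-analytic gradient agreement, per-tensor norm comparison.

    The floor absorbs parameters whose true gradient is identically zero
    (e.g. convolution biases absorbed by a following batch-norm), where both
    sides are pure finite-difference noise.
    """
    from dermapatch import nn

    def loss():
        l, _, _ = nn.softmax_cross_entropy(model.logits(x, training=True), y)
        return l

    logits = model.logits(x, training=True)
    _, _, d = nn.softmax_cross_entropy(logits, y)
    for p in model.params():
        p.grad[...] = 0.0
    model.backward(d)
    worst = 0.0
    for p in model.params():
        num = nn.numerical_gradient(loss, p)
        denom = max(np.linalg.norm(p.grad) + np.linalg.norm(num), floor)
        worst = max(worst, np.linalg.norm(p.grad - num) / denom)
    assert worst < tol, f"gradient mismatch: worst relative error {worst}"
    return worst
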