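"""Minimal numpy neural-network core: layers with exact forward/backward,
softmax cross-entropy, and Adam.

Conventions: 2-D feature maps are NHWC, 1-D sequences are NLC; convolutions
are stride-1 'same'. Every layer owns its parameters as `Param` objects and
implements `forward(x, training)` / `backward(grad)`; gradients accumulate
into `Param.grad`. All arithmetic stays in the dtype the parameters were
initialised with (float32 for speed, float64 for gradient checking).
"""

from __future__ import annotations

import numpy as np


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


def he_uniform(rng: np.random.Generator, shape, fan_in: int, dtype=np.float32) -> np.ndarray:
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    """Stride-1 'same' 2-D convolution, NHWC, kernel (kh, kw, Cin, Cout)."""

    def __init__(self, c_in: int, c_out: int, ksize: int, rng: np.random.Generator,
                 dtype=np.float32):
        k = int(ksize)
        fan_in = k * k * c_in
        self.W = Param(he_uniform(rng, (k, k, c_in, c_out), fan_in, dtype))
        self.b = Param(np.zeros(c_out, dtype=dtype))
        self.k = k

    def params(self):
        return [self.W, self.b]

    def forward(self, x, training=False):
        n, h, w, c_in = x.shape
        if c_in != self.W.value.shape[2]:
            raise ValueError(
                f"channel mismatch: input has {c_in}, kernel expects "
                f"{self.W.value.shape[2]}"
            )
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        self._xp, self._shape = xp, (n, h, w)
        c_out = self.W.value.shape[3]
        out = np.empty((n * h * w, c_out), dtype=x.dtype)
        out[:] = self.b.value
        for di in range(self.k):
            for dj in range(self.k):
                sl = xp[:, di:di + h, dj:dj + w, :].reshape(-1, c_in)
                out += sl @ self.W.value[di, dj]
        return out.reshape(n, h, w, c_out)

    def backward(self, grad):
        n, h, w = self._shape
        xp = self._xp
        c_in, c_out = self.W.value.shape[2:]
        g2 = grad.reshape(-1, c_out)
        self.b.grad += g2.sum(axis=0)
        dxp = np.zeros_like(xp)
        for di in range(self.k):
            for dj in range(self.k):
                sl = xp[:, di:di + h, dj:dj + w, :].reshape(-1, c_in)
                self.W.grad[di, dj] += sl.T @ g2
                dxp[:, di:di + h, dj:dj + w, :] += (g2 @ self.W.value[di, dj].T
                                                    ).reshape(n, h, w, c_in)
        p = self.k // 2
        return dxp[:, p:p + h, p:p + w, :] if p else dxp


class Conv1D(Layer):
    """Stride-1 'same' 1-D convolution, NLC, kernel (k, Cin, Cout)."""

    def __init__(self, c_in: int, c_out: int, ksize: int, rng: np.random.Generator,
                 dtype=np.float32):
        k = int(ksize)
        self.W = Param(he_uniform(rng, (k, c_in, c_out), k * c_in, dtype))
        self.b = Param(np.zeros(c_out, dtype=dtype))
        self.k = k

    def params(self):
        return [self.W, self.b]

    def forward(self, x, training=False):
        n, length, c_in = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (0, 0)))
        self._xp, self._shape = xp, (n, length)
        c_out = self.W.value.shape[2]
        out = np.empty((n * length, c_out), dtype=x.dtype)
        out[:] = self.b.value
        for d in range(self.k):
            out += xp[:, d:d + length, :].reshape(-1, c_in) @ self.W.value[d]
        return out.reshape(n, length, c_out)

    def backward(self, grad):
        n, length = self._shape
        xp = self._xp
        c_in, c_out = self.W.value.shape[1:]
        g2 = grad.reshape(-1, c_out)
        self.b.grad += g2.sum(axis=0)
        dxp = np.zeros_like(xp)
        for d in range(self.k):
            sl = xp[:, d:d + length, :].reshape(-1, c_in)
            self.W.grad[d] += sl.T @ g2
            dxp[:, d:d + length, :] += (g2 @ self.W.value[d].T).reshape(n, length, c_in)
        p = self.k // 2
        return dxp[:, p:p + length, :] if p else dxp


class BatchNorm(Layer):
    """Batch normalization over all axes but the last (channels).

    Training uses biased batch statistics and updates running moments with
    momentum 0.1; inference uses the running moments. The running moments are
    seeded from the first training batch rather than (0, 1), so short
    trainings on features of any scale still get consistent inference-mode
    statistics.
    """

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float32):
        self.gamma = Param(np.ones(channels, dtype=dtype))
        self.beta = Param(np.zeros(channels, dtype=dtype))
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.momentum = momentum
        self.eps = eps
        self.stats_seen = False

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, training=False):
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = 1.0 if not self.stats_seen else self.momentum
            self.stats_seen = True
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(x.dtype)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(x.dtype)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        self._cache = (xhat, inv, axes, training, x.shape)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, grad):
        xhat, inv, axes, training, shape = self._cache
        self.gamma.grad += (grad * xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        g = grad * self.gamma.value
        if not training:
            return g * inv
        m = np.prod([shape[a] for a in axes])
        # full batch-statistics backward
        return (inv / m) * (m * g - g.sum(axis=axes)
                            - xhat * (g * xhat).sum(axis=axes))


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.01):
        self.alpha = alpha

    def forward(self, x, training=False):
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, grad):
        return np.where(self._mask, grad, self.alpha * grad)


class Tanh(Layer):
    def forward(self, x, training=False):
        self._y = np.tanh(x)
        return self._y

    def backward(self, grad):
        return grad * (1.0 - self._y ** 2)


class MaxPool2D(Layer):
    """2x2 max pooling, stride 2; odd trailing rows/cols are dropped."""

    def forward(self, x, training=False):
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        xr = x[:, :h2 * 2, :w2 * 2, :].reshape(n, h2, 2, w2, 2, c)
        xr = xr.transpose(0, 1, 3, 2, 4, 5).reshape(n, h2, w2, 4, c)
        self._idx = xr.argmax(axis=3)
        self._inshape = x.shape
        return np.take_along_axis(xr, self._idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]

    def backward(self, grad):
        n, h, w, c = self._inshape
        h2, w2 = h // 2, w // 2
        dxr = np.zeros((n, h2, w2, 4, c), dtype=grad.dtype)
        np.put_along_axis(dxr, self._idx[:, :, :, None, :], grad[:, :, :, None, :], axis=3)
        dx = np.zeros((n, h, w, c), dtype=grad.dtype)
        dx[:, :h2 * 2, :w2 * 2, :] = (
            dxr.reshape(n, h2, w2, 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
            .reshape(n, h2 * 2, w2 * 2, c)
        )
        return dx


class GlobalAvgPool2D(Layer):
    """NHWC -> NC spatial mean (the 1x1 'GAP' reduction)."""

    def forward(self, x, training=False):
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, grad):
        n, h, w, c = self._shape
        return np.broadcast_to(grad[:, None, None, :], (n, h, w, c)) / (h * w)


class GlobalAvgPool1D(Layer):
    """NLC -> NC mean over positions."""

    def forward(self, x, training=False):
        self._shape = x.shape
        return x.mean(axis=1)

    def backward(self, grad):
        n, length, c = self._shape
        return np.broadcast_to(grad[:, None, :], (n, length, c)) / length


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, dtype=np.float32):
        self.W = Param(he_uniform(rng, (d_in, d_out), d_in, dtype))
        self.b = Param(np.zeros(d_out, dtype=dtype))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, training=False):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, grad):
        self.W.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value.T


class Dropout(Layer):
    """Inverted dropout; identity at inference. Uses its own seeded stream."""

    def __init__(self, rate: float, seed: int = 0):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0,1), got {rate}")
        self.rate = rate
        self.rng = np.random.default_rng(seed)

    def reseed(self, seed: int):
        self.rng = np.random.default_rng(seed)

    def forward(self, x, training=False):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Residual(Layer):
    """Skip connection: ReLU(inner(x) + x). Inner path must preserve shape."""

    def __init__(self, inner: list[Layer]):
        self.inner = inner
        self.relu = ReLU()

    def params(self):
        return [p for l in self.inner for p in l.params()]

    def forward(self, x, training=False):
        y = x
        for layer in self.inner:
            y = layer.forward(y, training)
        if y.shape != x.shape:
            raise ValueError(
                f"residual branch changed shape {x.shape} -> {y.shape}"
            )
        return self.relu.forward(y + x, training)

    def backward(self, grad):
        g = self.relu.backward(grad)
        gy = g
        for layer in reversed(self.inner):
            gy = layer.backward(gy)
        return gy + g


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


def softmax(z: np.ndarray) -> np.ndarray:
    """Row-wise softmax, shift-stable."""
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray,
                          class_weights: np.ndarray | None = None):
    """Mean cross-entropy and its gradient w.r.t. the logits.

    With ``class_weights`` (one weight per class) each example's loss term is
    scaled by the weight of its true class and the mean is weight-normalised,
    the usual correction for class-imbalanced training. Returns
    (loss, probs, dlogits); unweighted dlogits = (softmax - onehot)/N.
    """
    n = logits.shape[0]
    probs = softmax(logits.astype(np.float64))
    eps = 1e-12
    if class_weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(class_weights, dtype=np.float64)[labels]
    wsum = w.sum()
    loss = -np.sum(w * np.log(probs[np.arange(n), labels] + eps)) / wsum
    d = probs.copy()
    d[np.arange(n), labels] -= 1.0
    d *= (w / wsum)[:, None]
    return float(loss), probs, d.astype(logits.dtype)


class Adam:
    def __init__(self, params: list[Param], lr: float = 0.001, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        if lr <= 0:
            raise ValueError(f"learning rate must be > 0, got {lr}")
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1t, b2t = 1 - self.b1 ** self.t, 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * p.grad
            v[...] = self.b2 * v + (1 - self.b2) * p.grad ** 2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def numerical_gradient(loss_fn, param: Param, eps: float = 1e-5) -> np.ndarray:
    """Central finite differences of a scalar loss w.r.t. one Param."""
    g = np.zeros_like(param.value, dtype=np.float64)
    flat = param.value.reshape(-1)
    gf = g.reshape(-1)
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        lp = loss_fn()
        flat[i] = orig - eps
        lm = loss_fn()
        flat[i] = orig
        gf[i] = (lp - lm) / (2 * eps)
    return g


def iter_layers(root: Layer):
    """Depth-first walk over a layer tree (Sequential / Residual containers)."""
    yield root
    for attr in ("layers", "inner"):
        for sub in getattr(root, attr, []):
            yield from iter_layers(sub)


def get_state(root: Layer) -> list[np.ndarray]:
    """Copy every parameter (and batch-norm running moment) in walk order."""
    state = []
    for layer in iter_layers(root):
        for p in getattr(layer, "params", lambda: [])():
            if isinstance(layer, (Sequential, Residual)):
                break  # containers re-expose child params; skip duplicates
            state.append(p.value.copy())
        if isinstance(layer, BatchNorm):
            state.append(layer.running_mean.copy())
            state.append(layer.running_var.copy())
    return state


def set_state(root: Layer, state: list[np.ndarray]) -> None:
    it = iter(state)
    for layer in iter_layers(root):
        if isinstance(layer, (Sequential, Residual)):
            continue
        for p in layer.params():
            p.value[...] = next(it)
        if isinstance(layer, BatchNorm):
            layer.running_mean[...] = next(it)
            layer.running_var[...] = next(it)
            layer.stats_seen = True
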