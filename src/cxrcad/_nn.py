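"""Minimal numpy neural-network core.

Implements exactly the layer vocabulary the classifiers in
:mod:`cxrcad.model_zoo` need — 2-D convolution, batch normalization,
dropout, ReLU, average/max/adaptive-average pooling, flatten, linear,
residual and parallel-branch containers — with hand-written backward
passes and an Adam optimizer. Forward/backward correctness is checked
against finite differences in the test suite.

Arrays are ``(N, C, H, W)`` float32. Convolutions support two padding
policies: symmetric zero padding by a fixed amount (the classic
published architectures) and a ``"ceil"`` policy that pads only the
bottom/right edge so the output size is ``ceil(n / stride)`` — the
policy the 2x2/stride-2 custom blocks use, with edge replication so
even sizes halve exactly and odd sizes round up.
"""

from __future__ import annotations

import math

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import GeometryError


class Layer:
    """Base layer: parameter dict, gradient dict, forward/backward."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def walk(self):
        yield self


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, math.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


def _resolve_pad(n: int, k: int, s: int, padding) -> tuple[int, int]:
    """Per-axis (before, after) padding. int -> symmetric; 'ceil' ->
    bottom/right only, so out = ceil(n / s)."""
    if padding == "ceil":
        out = -(-n // s)
        total = max((out - 1) * s + k - n, 0)
        return 0, total
    return int(padding), int(padding)


class Conv2d(Layer):
    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int,
        stride: int = 1,
        padding=0,
        pad_mode: str = "constant",
        rng: np.random.Generator | None = None,
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.c_in, self.c_out, self.k, self.s = c_in, c_out, kernel, stride
        self.padding, self.pad_mode = padding, pad_mode
        fan_in = c_in * kernel * kernel
        self.params = {
            "W": _he_init(rng, (c_out, c_in, kernel, kernel), fan_in),
            "b": np.zeros(c_out, dtype=np.float32),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x, train=False, rng=None):
        n, c, h, w = x.shape
        pt, pb = _resolve_pad(h, self.k, self.s, self.padding)
        pl, pr = _resolve_pad(w, self.k, self.s, self.padding)
        self._pads = (pt, pb, pl, pr)
        self._in_shape = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr)), mode=self.pad_mode)
        win = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))[:, :, :: self.s, :: self.s]
        ho, wo = win.shape[2], win.shape[3]
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * self.k * self.k)
        self._cols, self._out_hw = cols, (ho, wo)
        wmat = self.params["W"].reshape(self.c_out, -1)
        y = cols @ wmat.T + self.params["b"]
        return np.ascontiguousarray(
            y.reshape(n, ho, wo, self.c_out).transpose(0, 3, 1, 2)
        )

    def backward(self, dy):
        n, _, h, w = self._in_shape
        ho, wo = self._out_hw
        pt, pb, pl, pr = self._pads
        k, s = self.k, self.s
        dyf = dy.transpose(0, 2, 3, 1).reshape(n * ho * wo, self.c_out)
        wmat = self.params["W"].reshape(self.c_out, -1)
        self.grads["W"][...] = (dyf.T @ self._cols).reshape(self.params["W"].shape)
        self.grads["b"][...] = dyf.sum(axis=0)
        dcols = (dyf @ wmat).reshape(n, ho, wo, self.c_in, k, k).transpose(0, 3, 1, 2, 4, 5)
        dxp = np.zeros((n, self.c_in, h + pt + pb, w + pl + pr), dtype=dy.dtype)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + s * ho : s, j : j + s * wo : s] += dcols[:, :, :, :, i, j]
        return _unpad_grad(dxp, (pt, pb, pl, pr), (h, w), self.pad_mode)


def _unpad_grad(dxp, pads, shape, mode):
    """Slice out the core gradient; for edge-replication padding, fold
    pad-region gradients back onto the border pixels they copied."""
    pt, pb, pl, pr = pads
    h, w = shape
    if mode == "edge":
        if pt:
            dxp[:, :, pt, :] += dxp[:, :, :pt, :].sum(axis=2)
        if pb:
            dxp[:, :, pt + h - 1, :] += dxp[:, :, pt + h :, :].sum(axis=2)
        dxp = dxp[:, :, pt : pt + h, :]
        if pl:
            dxp[:, :, :, pl] += dxp[:, :, :, :pl].sum(axis=3)
        if pr:
            dxp[:, :, :, pl + w - 1] += dxp[:, :, :, pl + w :].sum(axis=3)
        return dxp[:, :, :, pl : pl + w]
    return dxp[:, :, pt : pt + h, pl : pl + w]


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class BatchNorm2d(Layer):
    """Per-channel normalization: batch statistics in train mode,
    exponential running statistics in eval mode."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        super().__init__()
        self.c, self.momentum, self.eps = c, momentum, eps
        self.params = {
            "gamma": np.ones(c, dtype=np.float32),
            "beta": np.zeros(c, dtype=np.float32),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self._accumulate: list | None = None

    def forward(self, x, train=False, rng=None):
        axes = (0, 2, 3)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            if self._accumulate is not None:
                self._accumulate.append((mean, var))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps).astype(np.float32)
        self._xhat = (x - mean[:, None, None]) / self._std[:, None, None]
        self._train = train
        return self.params["gamma"][:, None, None] * self._xhat + self.params["beta"][:, None, None]

    def backward(self, dy):
        g = self.params["gamma"][:, None, None]
        axes = (0, 2, 3)
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        self.grads["gamma"][...] = (dy * self._xhat).sum(axis=axes)
        self.grads["beta"][...] = dy.sum(axis=axes)
        if not self._train:
            return dy * g / self._std[:, None, None]
        dxhat = dy * g
        mean_dxhat = dxhat.sum(axis=axes, keepdims=True) / m
        mean_dxhat_xhat = (dxhat * self._xhat).sum(axis=axes, keepdims=True) / m
        return (dxhat - mean_dxhat - self._xhat * mean_dxhat_xhat) / self._std[:, None, None]


def recalibrate_batchnorm(root: Layer, x: np.ndarray, batch_size: int = 256) -> None:
    """Replace every BatchNorm's running statistics with exact moments
    of the current weights over ``x`` ("precise BN").

    Runs forward passes in train mode with dropout disabled, collects
    per-batch channel moments, and combines them by the law of total
    variance. Makes inference consistent with the final weights instead
    of an exponential average that lags them.
    """
    bns = [l for l in root.walk() if isinstance(l, BatchNorm2d)]
    drops = [l for l in root.walk() if isinstance(l, Dropout)]
    if not bns:
        return
    rates = [d.rate for d in drops]
    for d in drops:
        d.rate = 0.0
    for bn in bns:
        bn._accumulate = []
    try:
        for i in range(0, x.shape[0], batch_size):
            root.forward(x[i : i + batch_size], train=True)
        for bn in bns:
            means = np.stack([m for m, _ in bn._accumulate])
            varis = np.stack([v for _, v in bn._accumulate])
            bn.running_mean = means.mean(axis=0).astype(np.float32)
            bn.running_var = (varis.mean(axis=0) + means.var(axis=0)).astype(np.float32)
    finally:
        for bn in bns:
            bn._accumulate = None
        for d, r in zip(drops, rates):
            d.rate = r


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float) -> None:
        super().__init__()
        self.rate = rate

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("Dropout in train mode needs an rng")
        self._mask = (rng.random(x.shape) >= self.rate).astype(x.dtype) / (1 - self.rate)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class AvgPool2d(Layer):
    """Non-overlapping k x k average pooling; spatial dims must divide."""

    def __init__(self, k: int) -> None:
        super().__init__()
        self.k = k

    def forward(self, x, train=False, rng=None):
        n, c, h, w = x.shape
        if h % self.k or w % self.k:
            raise GeometryError(f"AvgPool2d({self.k}): input {h}x{w} not divisible")
        self._in_shape = x.shape
        return x.reshape(n, c, h // self.k, self.k, w // self.k, self.k).mean(axis=(3, 5))

    def backward(self, dy):
        k = self.k
        return np.repeat(np.repeat(dy, k, axis=2), k, axis=3) / (k * k)


class GlobalAvgPool(Layer):
    def forward(self, x, train=False, rng=None):
        self._in_shape = x.shape
        return x.mean(axis=(2, 3), keepdims=True)

    def backward(self, dy):
        n, c, h, w = self._in_shape
        return np.broadcast_to(dy / (h * w), self._in_shape).copy()


class AdaptiveAvgPool2d(Layer):
    """Average pooling onto a fixed output grid with torch-style bins."""

    def __init__(self, out: int) -> None:
        super().__init__()
        self.out = out

    @staticmethod
    def _bins(n: int, out: int):
        return [(int(math.floor(i * n / out)), int(math.ceil((i + 1) * n / out))) for i in range(out)]

    def forward(self, x, train=False, rng=None):
        n, c, h, w = x.shape
        self._in_shape = x.shape
        rb, cb = self._bins(h, self.out), self._bins(w, self.out)
        self._rb, self._cb = rb, cb
        y = np.empty((n, c, self.out, self.out), dtype=x.dtype)
        for i, (r0, r1) in enumerate(rb):
            for j, (c0, c1) in enumerate(cb):
                y[:, :, i, j] = x[:, :, r0:r1, c0:c1].mean(axis=(2, 3))
        return y

    def backward(self, dy):
        dx = np.zeros(self._in_shape, dtype=dy.dtype)
        for i, (r0, r1) in enumerate(self._rb):
            for j, (c0, c1) in enumerate(self._cb):
                area = (r1 - r0) * (c1 - c0)
                dx[:, :, r0:r1, c0:c1] += dy[:, :, i, j][:, :, None, None] / area
        return dx


class MaxPool2d(Layer):
    def __init__(self, k: int, stride: int | None = None, padding=0) -> None:
        super().__init__()
        self.k = k
        self.s = stride or k
        self.padding = padding

    def forward(self, x, train=False, rng=None):
        n, c, h, w = x.shape
        pt, pb = _resolve_pad(h, self.k, self.s, self.padding)
        pl, pr = _resolve_pad(w, self.k, self.s, self.padding)
        self._pads, self._in_shape = (pt, pb, pl, pr), x.shape
        xp = np.pad(
            x, ((0, 0), (0, 0), (pt, pb), (pl, pr)),
            mode="constant", constant_values=-np.inf,
        )
        self._padded_shape = xp.shape
        win = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))[:, :, :: self.s, :: self.s]
        ho, wo = win.shape[2], win.shape[3]
        flat = win.reshape(n, c, ho, wo, self.k * self.k)
        self._argmax = flat.argmax(axis=4)
        self._out_hw = (ho, wo)
        return flat.max(axis=4)

    def backward(self, dy):
        n, c, h, w = self._in_shape
        pt, pb, pl, pr = self._pads
        ho, wo = self._out_hw
        dxp = np.zeros(self._padded_shape, dtype=dy.dtype)
        ni, ci, ri, cj = np.indices((n, c, ho, wo))
        rr = ri * self.s + self._argmax // self.k
        cc = cj * self.s + self._argmax % self.k
        np.add.at(dxp, (ni, ci, rr, cc), dy)
        return dxp[:, :, pt : pt + h, pl : pl + w]


class Flatten(Layer):
    def forward(self, x, train=False, rng=None):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._in_shape)


class Linear(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.d_in, self.d_out = d_in, d_out
        self.params = {
            "W": _he_init(rng, (d_out, d_in), d_in),
            "b": np.zeros(d_out, dtype=np.float32),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, dy):
        self.grads["W"][...] = dy.T @ self._x
        self.grads["b"][...] = dy.sum(axis=0)
        return dy @ self.params["W"]


class Sequential(Layer):
    def __init__(self, layers: list[Layer]) -> None:
        super().__init__()
        self.layers = layers

    def forward(self, x, train=False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def n_params(self) -> int:
        return sum(l.n_params() for l in self.layers)

    def walk(self):
        for layer in self.layers:
            yield from layer.walk()


class Branches(Layer):
    """Parallel branches concatenated along the channel axis (inception)."""

    def __init__(self, branches: list[Sequential]) -> None:
        super().__init__()
        self.branches = branches

    def forward(self, x, train=False, rng=None):
        outs = [b.forward(x, train=train, rng=rng) for b in self.branches]
        self._splits = np.cumsum([o.shape[1] for o in outs])[:-1]
        return np.concatenate(outs, axis=1)

    def backward(self, dy):
        parts = np.split(dy, self._splits, axis=1)
        dx = self.branches[0].backward(parts[0])
        for b, p in zip(self.branches[1:], parts[1:]):
            dx = dx + b.backward(p)
        return dx

    def n_params(self) -> int:
        return sum(b.n_params() for b in self.branches)

    def walk(self):
        for b in self.branches:
            yield from b.walk()


class Residual(Layer):
    """y = relu(body(x) + shortcut(x)); identity shortcut when None."""

    def __init__(self, body: Sequential, shortcut: Sequential | None = None) -> None:
        super().__init__()
        self.body = body
        self.shortcut = shortcut

    def forward(self, x, train=False, rng=None):
        pre = self.body.forward(x, train=train, rng=rng)
        skip = x if self.shortcut is None else self.shortcut.forward(x, train=train, rng=rng)
        self._pre = pre + skip
        return self._pre * (self._pre > 0)

    def backward(self, dy):
        d = dy * (self._pre > 0)
        dx = self.body.backward(d)
        if self.shortcut is None:
            return dx + d
        return dx + self.shortcut.backward(d)

    def n_params(self) -> int:
        return self.body.n_params() + (self.shortcut.n_params() if self.shortcut else 0)

    def walk(self):
        yield from self.body.walk()
        if self.shortcut is not None:
            yield from self.shortcut.walk()


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, y: np.ndarray, sample_weight: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    """Weighted mean cross-entropy of integer targets ``y``.

    Returns (loss, dlogits). ``sample_weight`` rescales each example's
    contribution (normalized by the weight sum), e.g. to upweight the
    positive class.
    """
    n = logits.shape[0]
    p = softmax(logits)
    nll = -np.log(np.clip(p[np.arange(n), y], 1e-12, None))
    dlogits = p
    dlogits[np.arange(n), y] -= 1.0
    if sample_weight is None:
        return float(nll.mean()), dlogits / n
    w = sample_weight / sample_weight.sum()
    return float((nll * w).sum()), dlogits * w[:, None]


class Adam:
    """Adam with the standard bias correction; updates in place.
    ``weight_decay`` is decoupled shrinkage applied to weight matrices
    only (not biases, not batch-norm scale/shift)."""

    def __init__(self, root: Layer, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8,
                 weight_decay: float = 0.0) -> None:
        self.slots = [
            (layer, key) for layer in root.walk() for key in layer.params
        ]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(layer.params[k]) for layer, k in self.slots]
        self.v = [np.zeros_like(layer.params[k]) for layer, k in self.slots]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for i, (layer, key) in enumerate(self.slots):
            g = layer.grads[key]
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            layer.params[key] -= self.lr * (self.m[i] / b1t) / (
                np.sqrt(self.v[i] / b2t) + self.eps
            )
            if self.weight_decay and key == "W":
                layer.params[key] -= self.lr * self.weight_decay * layer.params[key]
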