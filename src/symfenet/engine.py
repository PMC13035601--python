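"""Minimal transparent NumPy layers for 3D volume networks.

Every layer is an object with ``forward(x, train=False, rng=None)`` and
``backward(grad)``; parameters and their gradients live in ``params`` /
``grads`` dicts so optimizers and checkpoints can address them by name.
Batched arrays are laid out ``(N, W, H, D, C)`` in float32.  The design is
deliberately explicit — convolutions are 27 slice-matmul accumulations, the
adjoint of every geometric rearrangement is written out by hand — so that
each step can be checked against brute-force voxel oracles and
finite-difference gradients.
"""

from __future__ import annotations

from typing import Dict, Optional

import numpy as np

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    _HAVE_NUMBA = False

    def njit(*a, **k):
        def deco(f):
            return f
        return deco


@njit(cache=True, fastmath=True)
def _conv3d_fwd_kernel(xpad, wt, out):
    n, wp, hp, dp, ci = xpad.shape
    k = wt.shape[0]
    co = wt.shape[4]
    w, h, d = wp - k + 1, hp - k + 1, dp - k + 1
    acc = np.zeros(co, dtype=np.float32)
    for b in range(n):
        for x in range(w):
            for y in range(h):
                for z in range(d):
                    for o in range(co):
                        acc[o] = 0.0
                    for i in range(k):
                        for j in range(k):
                            row = xpad[b, x + i, y + j]
                            for l in range(k):
                                for c in range(ci):
                                    v = row[z + l, c]
                                    for o in range(co):
                                        acc[o] += v * wt[i, j, l, c, o]
                    for o in range(co):
                        out[b, x, y, z, o] = acc[o]


@njit(cache=True, fastmath=True)
def _conv3d_bwd_kernel(xpad, wt, g, dW, dxpad):
    n, wp, hp, dp, ci = xpad.shape
    k = wt.shape[0]
    co = wt.shape[4]
    w, h, d = wp - k + 1, hp - k + 1, dp - k + 1
    for b in range(n):
        for x in range(w):
            for y in range(h):
                for z in range(d):
                    for i in range(k):
                        for j in range(k):
                            for l in range(k):
                                for c in range(ci):
                                    v = xpad[b, x + i, y + j, z + l, c]
                                    acc = np.float32(0.0)
                                    for o in range(co):
                                        gv = g[b, x, y, z, o]
                                        dW[i, j, l, c, o] += v * gv
                                        acc += gv * wt[i, j, l, c, o]
                                    dxpad[b, x + i, y + j, z + l, c] += acc

__all__ = [
    "Conv3D",
    "ReLU",
    "SpatialDropout3D",
    "MaxPool3D",
    "GlobalAvgPool",
    "Dense",
    "softmax",
    "softmax_cross_entropy",
    "Adam",
]


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Layer:
    """Base: a parameterized differentiable map."""

    def __init__(self):
        self.params: Dict[str, np.ndarray] = {}
        self.grads: Dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False,
                rng: Optional[np.random.Generator] = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv3D(Layer):
    """3D convolution with 'same' zero padding.

    Weight shape ``(k, k, k, C_in, C_out)``.  Implementation detail: the
    zero-padded volume is viewed as a flat ``(N, Wp·Hp·Dp, C)`` array, in
    which every kernel tap is a constant flat offset; the convolution is
    then k³ contiguous-slice batched matmuls, with no im2col gather.  The
    flat-offset arithmetic is exact for all interior voxels, and the border
    rows of the padded accumulator (the only ones a wrapped offset could
    touch) are discarded on extraction.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 kernel_size: int = 3, bias: bool = True):
        super().__init__()
        self.k = kernel_size
        self.c_in, self.c_out = c_in, c_out
        fan_in = kernel_size ** 3 * c_in
        self.params["W"] = _he_init(rng, (kernel_size,) * 3 + (c_in, c_out), fan_in)
        self.use_bias = bias
        if bias:
            self.params["b"] = np.zeros(c_out, dtype=np.float32)
        self._xflat: Optional[np.ndarray] = None

    def _offsets(self, hp: int, dp: int):
        p = self.k // 2
        for i in range(self.k):
            for j in range(self.k):
                for l in range(self.k):
                    yield i, j, l, ((i - p) * hp + (j - p)) * dp + (l - p)

    def forward(self, x, train=False, rng=None):
        x = np.ascontiguousarray(x, dtype=np.float32)
        n, w, h, d, c = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} channels, got {c}")
        p = self.k // 2
        wp, hp, dp = w + 2 * p, h + 2 * p, d + 2 * p
        xpad = np.zeros((n, wp, hp, dp, c), dtype=np.float32)
        xpad[:, p:p + w, p:p + h, p:p + d] = x
        # direct kernels win for narrow channel counts, BLAS for wide ones
        self._use_numba = _HAVE_NUMBA and self.c_in * self.c_out <= 64
        if self._use_numba:
            out = np.zeros((n, w, h, d, self.c_out), dtype=np.float32)
            _conv3d_fwd_kernel(xpad, self.params["W"], out)
            self._xpad, self._dims = xpad, (n, w, h, d, wp, hp, dp)
            if self.use_bias:
                out += self.params["b"]
            return out
        # collapse batch and space: padded border rows are zero, so a tap
        # offset that crosses a sample boundary only ever reads zeros or
        # writes into border rows that are discarded on extraction
        tot = n * wp * hp * dp
        xflat = xpad.reshape(tot, c)
        out = np.zeros((tot, self.c_out), dtype=np.float32)
        wt = self.params["W"]
        for i, j, l, r in self._offsets(hp, dp):
            lo, hi = max(0, -r), tot - max(0, r)
            out[lo:hi] += xflat[lo + r:hi + r] @ wt[i, j, l]
        self._xflat, self._dims = xflat, (n, w, h, d, wp, hp, dp)
        out = out.reshape(n, wp, hp, dp, self.c_out)[
            :, p:p + w, p:p + h, p:p + d]
        if self.use_bias:
            out += self.params["b"]
        return np.ascontiguousarray(out)

    def backward(self, grad):
        n, w, h, d, wp, hp, dp = self._dims
        p = self.k // 2
        if self._use_numba:
            g = np.ascontiguousarray(grad, dtype=np.float32)
            dW = np.zeros_like(self.params["W"])
            dxpad = np.zeros_like(self._xpad)
            _conv3d_bwd_kernel(self._xpad, self.params["W"], g, dW, dxpad)
            self.grads["W"] = dW
            if self.use_bias:
                self.grads["b"] = g.reshape(-1, self.c_out).sum(axis=0)
            self._xpad = None
            return np.ascontiguousarray(
                dxpad[:, p:p + w, p:p + h, p:p + d])
        tot = n * wp * hp * dp
        gpad = np.zeros((n, wp, hp, dp, self.c_out), dtype=np.float32)
        gpad[:, p:p + w, p:p + h, p:p + d] = grad
        gflat = gpad.reshape(tot, self.c_out)
        xflat = self._xflat
        wt = self.params["W"]
        dW = np.zeros_like(wt)
        dx = np.zeros_like(xflat)
        for i, j, l, r in self._offsets(hp, dp):
            lo, hi = max(0, -r), tot - max(0, r)
            gs = gflat[lo:hi]
            dW[i, j, l] = xflat[lo + r:hi + r].T @ gs
            dx[lo + r:hi + r] += gs @ wt[i, j, l].T
        self.grads["W"] = dW
        if self.use_bias:
            self.grads["b"] = gflat.sum(axis=0)
        self._xflat = None
        return np.ascontiguousarray(
            dx.reshape(n, wp, hp, dp, self.c_in)[:, p:p + w, p:p + h, p:p + d])


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, grad):
        return np.where(self._mask, grad, 0.0).astype(np.float32)


class SpatialDropout3D(Layer):
    """Channel-wise (spatial) dropout with inverted scaling.

    In training, each feature channel of each sample is zeroed independently
    with probability ``p`` and survivors are scaled by ``1/(1-p)``; the mask
    is constant over the spatial extent of a channel.  Evaluation is the
    identity.
    """

    def __init__(self, p: float):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0, 1), got {p}")
        self.p = p

    def forward(self, x, train=False, rng=None):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout requires an rng")
        n, _, _, _, c = x.shape
        keep = (rng.random((n, 1, 1, 1, c)) >= self.p).astype(np.float32)
        self._mask = keep / (1.0 - self.p)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class MaxPool3D(Layer):
    """Non-overlapping max pooling with cubic window ``f``; extents must divide."""

    def __init__(self, factor: int = 2):
        super().__init__()
        self.f = factor

    def forward(self, x, train=False, rng=None):
        f = self.f
        n, w, h, d, c = x.shape
        if w % f or h % f or d % f:
            raise ValueError(f"spatial extents {x.shape[1:4]} not divisible by {f}")
        xr = x.reshape(n, w // f, f, h // f, f, d // f, f, c)
        xr = xr.transpose(0, 1, 3, 5, 7, 2, 4, 6).reshape(
            n, w // f, h // f, d // f, c, f ** 3)
        idx = xr.argmax(axis=-1)
        self._shape = x.shape
        self._idx = idx
        return np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def backward(self, grad):
        f = self.f
        n, w, h, d, c = self._shape
        gwin = np.zeros((n, w // f, h // f, d // f, c, f ** 3), dtype=np.float32)
        np.put_along_axis(gwin, self._idx[..., None], grad[..., None], axis=-1)
        gwin = gwin.reshape(n, w // f, h // f, d // f, c, f, f, f)
        gwin = gwin.transpose(0, 1, 5, 2, 6, 3, 7, 4)
        return np.ascontiguousarray(gwin.reshape(n, w, h, d, c))


class GlobalAvgPool(Layer):
    """Mean over the three spatial axes: ``(N,W,H,D,C) -> (N,C)``."""

    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.mean(axis=(1, 2, 3))

    def backward(self, grad):
        n, w, h, d, c = self._shape
        return np.broadcast_to(
            grad[:, None, None, None, :] / (w * h * d), self._shape
        ).copy()


class BatchNorm(Layer):
    """Per-channel batch normalization over all axes but the last.

    Training uses batch statistics and maintains exponential running
    estimates (momentum 0.9) used at evaluation, so eval-mode forward is a
    deterministic function of the input and the trained state.  Learnable
    scale/shift per channel.
    """

    def __init__(self, channels: int, momentum: float = 0.9,
                 eps: float = 1e-5):
        super().__init__()
        self.params["gamma"] = np.ones(channels, dtype=np.float32)
        self.params["beta"] = np.zeros(channels, dtype=np.float32)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, train=False, rng=None):
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mean
            self.running_var = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps).astype(np.float32)
        xhat = (x - mean) / std
        self._xhat, self._std, self._axes = xhat, std, axes
        self._m = x.size // x.shape[-1]
        self._train = train
        return (self.params["gamma"] * xhat + self.params["beta"]).astype(
            np.float32)

    def backward(self, grad):
        xhat, std, axes = self._xhat, self._std, self._axes
        self.grads["gamma"] = (grad * xhat).sum(axis=axes)
        self.grads["beta"] = grad.sum(axis=axes)
        g = self.params["gamma"] / std
        if not self._train:
            return (grad * g).astype(np.float32)
        m = self._m
        return (g * (grad - self.grads["beta"] / m
                     - xhat * self.grads["gamma"] / m)).astype(np.float32)


class Dense(Layer):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        self.params["W"] = _he_init(rng, (c_in, c_out), c_in)
        self.params["b"] = np.zeros(c_out, dtype=np.float32)

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, grad):
        self.grads["W"] = self._x.T @ grad
        self.grads["b"] = grad.sum(axis=0)
        return grad @ self.params["W"].T


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy over the batch; returns ``(loss, dlogits)``."""
    n = logits.shape[0]
    p = softmax(logits)
    eps = np.finfo(np.float32).tiny
    loss = -np.log(p[np.arange(n), labels] + eps).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return float(loss), (dlogits / n).astype(np.float32)


class Adam:
    """Adam over a flat ``{name: array}`` parameter dict."""

    def __init__(self, params: Dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: Dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            p -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)
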