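"""Compact CPU neural-network engine used by the segmentation models.

Implements exactly the operations a VGG-style fully convolutional network
needs — 2-D convolution (im2col/col2im), 2×2 max pooling, ReLU, strided
transposed convolution for learnable bilinear upsampling, softmax
cross-entropy with an ignore index, and SGD with momentum — in plain numpy,
with hand-derived backward passes.  Arrays are NCHW throughout.  Every layer
is deterministic: two forwards with the same weights and input are
bit-identical, which the training and checkpoint contracts rely on.

The engine is validated by finite-difference gradient checks in the test
suite; it favours clarity and predictable memory use over peak speed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Param:
    """A learnable tensor and its accumulated gradient."""

    name: str
    data: np.ndarray
    grad: np.ndarray = field(init=False)
    lr_scale: float = 1.0

    def __post_init__(self) -> None:
        self.grad = np.zeros_like(self.data)


# ---------------------------------------------------------------------------
# im2col / col2im
# ---------------------------------------------------------------------------

def _out_size(size: int, k: int, stride: int, pad: int) -> int:
    return (size + 2 * pad - k) // stride + 1


def im2col(x: np.ndarray, k: int, stride: int, pad: int) -> np.ndarray:
    """Unfold NCHW ``x`` into (N, C*k*k, Ho*Wo) patch columns."""
    n, c, h, w = x.shape
    ho, wo = _out_size(h, k, stride, pad), _out_size(w, k, stride, pad)
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = np.empty((n, c, k, k, ho, wo), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = x[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride]
    return cols.reshape(n, c * k * k, ho * wo)


def col2im(cols: np.ndarray, x_shape: tuple[int, ...], k: int, stride: int,
           pad: int) -> np.ndarray:
    """Adjoint of :func:`im2col`: scatter-add columns back into NCHW shape."""
    n, c, h, w = x_shape
    ho, wo = _out_size(h, k, stride, pad), _out_size(w, k, stride, pad)
    cols = cols.reshape(n, c, k, k, ho, wo)
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    for i in range(k):
        for j in range(k):
            xp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += cols[:, :, i, j]
    return xp[:, :, pad : pad + h, pad : pad + w] if pad else xp


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class Conv2d(Layer):
    """k×k convolution, stride 1, 'same' padding by default.

    ``init`` selects the weight initialisation: ``"he"`` (ReLU-scaled
    Gaussian), ``"dirac"`` (identity pass-through plus scaled-down He noise —
    keeps the input signal, e.g. colour, intact through deep untrained
    stacks, which is what makes from-scratch training converge quickly), or
    ``"zero"`` (for score/skip heads).
    """

    def __init__(self, in_ch: int, out_ch: int, k: int, pad: int | None = None,
                 name: str = "conv", rng: np.random.Generator | None = None,
                 init: str = "he", lr_scale: float = 1.0):
        self.k, self.pad = k, (k // 2 if pad is None else pad)
        self.in_ch, self.out_ch = in_ch, out_ch
        fan_in = in_ch * k * k
        he_std = np.sqrt(2.0 / fan_in)
        if init == "zero":
            w = np.zeros((out_ch, in_ch, k, k), dtype=np.float32)
        elif init == "he":
            rng = rng or np.random.default_rng(0)
            w = rng.normal(0.0, he_std, (out_ch, in_ch, k, k)).astype(np.float32)
        elif init == "dirac":
            rng = rng or np.random.default_rng(0)
            w = rng.normal(0.0, 0.3 * he_std, (out_ch, in_ch, k, k)).astype(np.float32)
            for o in range(out_ch):
                w[o, o % in_ch, k // 2, k // 2] += 1.0
        else:
            raise ValueError(f"unknown init: {init!r}")
        self.w = Param(f"{name}.w", w, lr_scale=lr_scale)
        self.b = Param(f"{name}.b", np.zeros(out_ch, dtype=np.float32), lr_scale=lr_scale)
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        ho, wo = _out_size(h, self.k, 1, self.pad), _out_size(w, self.k, 1, self.pad)
        cols = im2col(x, self.k, 1, self.pad)
        wf = self.w.data.reshape(self.out_ch, -1)
        y = np.matmul(wf, cols) + self.b.data[:, None]
        self._cache = (x.shape, cols)
        return y.reshape(n, self.out_ch, ho, wo)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x_shape, cols = self._cache
        n = dy.shape[0]
        dyf = dy.reshape(n, self.out_ch, -1)
        self.w.grad += np.einsum("nol,nkl->ok", dyf, cols).reshape(self.w.data.shape)
        self.b.grad += dyf.sum(axis=(0, 2))
        dcols = np.matmul(self.w.data.reshape(self.out_ch, -1).T, dyf)
        self._cache = None
        return col2im(dcols, x_shape, self.k, 1, self.pad)


class ConvTranspose2d(Layer):
    """Strided transposed convolution; the learnable upsampling layer.

    Weight shape is (in_ch, out_ch, k, k).  With ``bilinear_init`` the kernel
    is the standard bilinear interpolation filter replicated per channel, so
    before any training the layer performs plain bilinear upsampling.
    """

    def __init__(self, in_ch: int, out_ch: int, k: int, stride: int,
                 pad: int, name: str = "up", bilinear_init: bool = True,
                 frozen: bool = False):
        self.k, self.stride, self.pad = k, stride, pad
        self.in_ch, self.out_ch = in_ch, out_ch
        w = np.zeros((in_ch, out_ch, k, k), dtype=np.float32)
        if bilinear_init:
            filt = bilinear_kernel(k)
            for i in range(min(in_ch, out_ch)):
                w[i, i] = filt
        self.w = Param(f"{name}.w", w, lr_scale=0.0 if frozen else 1.0)
        self.b = Param(f"{name}.b", np.zeros(out_ch, dtype=np.float32),
                       lr_scale=0.0 if frozen else 1.0)
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def out_shape(self, h: int, w: int) -> tuple[int, int]:
        s, k, p = self.stride, self.k, self.pad
        return ((h - 1) * s + k - 2 * p, (w - 1) * s + k - 2 * p)

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        ho, wo = self.out_shape(h, w)
        xf = x.reshape(n, c, h * w)
        cols = np.matmul(self.w.data.reshape(self.in_ch, -1).T, xf)
        y = col2im(cols, (n, self.out_ch, ho, wo), self.k, self.stride, self.pad)
        y += self.b.data[None, :, None, None]
        self._cache = (xf, (n, c, h, w))
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xf, x_shape = self._cache
        dcols = im2col(dy, self.k, self.stride, self.pad)
        self.w.grad += np.einsum("ncl,nkl->ck", xf, dcols).reshape(self.w.data.shape)
        self.b.grad += dy.sum(axis=(0, 2, 3))
        dxf = np.matmul(self.w.data.reshape(self.in_ch, -1), dcols)
        self._cache = None
        return dxf.reshape(x_shape)


class MaxPool2d(Layer):
    """2×2 max pooling, stride 2; input spatial dims must be even."""

    def __init__(self) -> None:
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"MaxPool2d needs even spatial dims, got {h}×{w}")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // 2, w // 2, 4)
        idx = np.argmax(xr, axis=4)
        y = np.take_along_axis(xr, idx[..., None], axis=4)[..., 0]
        self._cache = (x.shape, idx)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        (n, c, h, w), idx = self._cache
        dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=dy.dtype)
        np.put_along_axis(dxr, idx[..., None], dy[..., None], axis=4)
        dx = dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        self._cache = None
        return dx.reshape(n, c, h, w)


class ReLU(Layer):
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = np.where(self._mask, dy, 0)
        self._mask = None
        return dx


class Sequential(Layer):
    def __init__(self, *layers: Layer) -> None:
        self.layers = list(layers)

    def params(self) -> list[Param]:
        return [p for l in self.layers for p in l.params()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


# ---------------------------------------------------------------------------
# Functional pieces
# ---------------------------------------------------------------------------

def bilinear_kernel(k: int) -> np.ndarray:
    """k×k bilinear interpolation kernel (the classical FCN upsampler init)."""
    factor = (k + 1) // 2
    center = factor - 1 if k % 2 == 1 else factor - 0.5
    og = np.arange(k, dtype=np.float64)
    filt1d = 1.0 - np.abs(og - center) / factor
    return np.outer(filt1d, filt1d).astype(np.float32)


def softmax(scores: np.ndarray, axis: int = 1) -> np.ndarray:
    z = scores - scores.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(scores: np.ndarray, labels: np.ndarray,
                          ignore_code: int = 255) -> tuple[float, np.ndarray]:
    """Mean per-pixel cross-entropy over non-ignored pixels, and its gradient.

    ``scores`` is (N, K, H, W) logits, ``labels`` (N, H, W) integer codes.
    Ignored pixels contribute neither to the loss nor to the gradient, so a
    batch's loss is unchanged by adding ignore-labeled pixels.
    """
    n, k, h, w = scores.shape
    valid = labels != ignore_code
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("no labeled (non-ignore) pixels in batch")
    p = softmax(scores, axis=1)
    lab = np.where(valid, labels, 0).astype(np.int64)
    onehot_p = np.take_along_axis(p, lab[:, None], axis=1)[:, 0]
    logp = np.log(np.maximum(onehot_p, 1e-30))
    loss = float(-(logp * valid).sum() / n_valid)
    grad = p.copy()
    np.put_along_axis(grad, lab[:, None], (onehot_p - 1.0)[:, None], axis=1)
    grad *= (valid[:, None] / n_valid).astype(scores.dtype)
    return loss, grad.astype(scores.dtype)


class Adam:
    """Adam with decoupled weight decay; the default for from-scratch training."""

    def __init__(self, params: list[Param], lr: float = 2e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.beta1 ** self.t
        bc2 = 1.0 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.lr_scale == 0.0:
                continue
            g = p.grad
            if self.weight_decay and p.data.ndim > 1:
                g = g + self.weight_decay * p.data
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p.data -= self.lr * p.lr_scale * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


class SGD:
    """Stochastic gradient descent with momentum and decoupled weight decay."""

    def __init__(self, params: list[Param], lr: float, momentum: float = 0.9,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self.velocity = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        for p, v in zip(self.params, self.velocity):
            if p.lr_scale == 0.0:
                continue
            g = p.grad
            if self.weight_decay and p.data.ndim > 1:  # no decay on biases
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v -= self.lr * p.lr_scale * g
            p.data += v
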