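"""Minimal NumPy neural-network framework for 3D fully-convolutional nets.

Layers operate on arrays shaped (batch, channels, x, y, z) and implement
explicit forward/backward passes; parameters carry their own gradients and
are updated by an Adam optimizer. Everything is seeded through a
``numpy.random.Generator``, so training is deterministic for a fixed seed
(single-threaded).

The framework is deliberately small: 3D convolution (kernel 1, 2-transposed
or 3, stride 1, same padding), batch normalization, ReLU, dropout, 2x max
pooling, 2x nearest-neighbour upsampling, and a softmax + soft-dice loss
head. That is exactly the vocabulary a UNet needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


#: Compute dtype of the framework; float32 keeps the matmuls in sgemm.
DTYPE = np.float32


class Param:
    """A trainable array with its accumulated gradient."""

    __slots__ = ("value", "grad", "trainable", "name")

    def __init__(self, value: np.ndarray, name: str = "", trainable=True):
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)
        self.trainable = trainable
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size

    def zero_grad(self):
        self.grad[...] = 0.0


class Layer:
    """Base layer: subclasses cache what backward needs during forward."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _he_init(rng: np.random.Generator, shape, fan_in) -> np.ndarray:
    return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)


class Conv3d(Layer):
    """3D convolution, stride 1, zero 'same' padding, kernel 1 or 3.

    The 3x3x3 case is computed as 27 shifted-slice matrix products
    (one per kernel offset), which keeps the memory access pattern
    contiguous instead of materializing a full im2col matrix.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator, name: str = "conv"):
        if kernel not in (1, 3):
            raise ValueError("Conv3d supports kernel sizes 1 and 3")
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        fan_in = in_ch * kernel ** 3
        self.weight = Param(_he_init(rng, (kernel ** 3, in_ch, out_ch),
                                     fan_in), f"{name}.weight")
        self.bias = Param(np.zeros(out_ch), f"{name}.bias")
        self._xp = None
        self._x_shape = None

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x, train):
        x = np.ascontiguousarray(x, dtype=DTYPE)
        self._x_shape = x.shape
        b, c, d, h, w = x.shape
        if self.kernel == 1:
            self._xp = x
            flat = x.transpose(0, 2, 3, 4, 1).reshape(-1, c)
            out = flat @ self.weight.value[0] + self.bias.value
            return np.ascontiguousarray(
                out.reshape(b, d, h, w, self.out_ch).transpose(0, 4, 1, 2, 3))
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1), (1, 1)))
        self._xp = xp
        out = np.zeros((b, d, h, w, self.out_ch), dtype=DTYPE)
        for o, (i, j, k) in enumerate(np.ndindex(3, 3, 3)):
            seg = xp[:, :, i:i + d, j:j + h, k:k + w]
            seg = seg.reshape(b, c, -1).transpose(0, 2, 1)
            out += (seg @ self.weight.value[o]).reshape(b, d, h, w,
                                                        self.out_ch)
        out += self.bias.value
        return np.ascontiguousarray(out.transpose(0, 4, 1, 2, 3))

    def backward(self, grad):
        b, c, d, h, w = self._x_shape
        grad = np.ascontiguousarray(grad, dtype=DTYPE)
        gflat = grad.transpose(0, 2, 3, 4, 1).reshape(b, -1, self.out_ch)
        self.bias.grad += gflat.sum(axis=(0, 1))
        if self.kernel == 1:
            x = self._xp
            xf = x.reshape(b, c, -1)
            self.weight.grad[0] += np.einsum("bcn,bno->co", xf, gflat,
                                             optimize=True)
            gx = (gflat @ self.weight.value[0].T).transpose(0, 2, 1)
            return gx.reshape(b, c, d, h, w)
        xp = self._xp
        gxp = np.zeros_like(xp)
        for o, (i, j, k) in enumerate(np.ndindex(3, 3, 3)):
            seg = xp[:, :, i:i + d, j:j + h, k:k + w].reshape(b, c, -1)
            self.weight.grad[o] += np.einsum("bcn,bno->co", seg, gflat,
                                             optimize=True)
            gseg = (gflat @ self.weight.value[o].T).transpose(0, 2, 1)
            gxp[:, :, i:i + d, j:j + h, k:k + w] += gseg.reshape(
                b, c, d, h, w)
        return gxp[:, :, 1:-1, 1:-1, 1:-1]


class ConvTranspose3d(Layer):
    """Transposed convolution with kernel 2 and stride 2 (exact 2x
    upsampling; output blocks do not overlap)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator,
                 name: str = "convT"):
        self.in_ch, self.out_ch = in_ch, out_ch
        self.weight = Param(_he_init(rng, (in_ch, out_ch, 2, 2, 2), in_ch),
                            f"{name}.weight")
        self.bias = Param(np.zeros(out_ch), f"{name}.bias")
        self._x = None

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x, train):
        self._x = x
        b, c, d, h, w = x.shape
        y = np.einsum("bcdhw,coijk->bodihjwk", x, self.weight.value,
                      optimize=True)
        y = y.reshape(b, self.out_ch, 2 * d, 2 * h, 2 * w)
        return y + self.bias.value[None, :, None, None, None]

    def backward(self, grad):
        b, o, D, H, W = grad.shape
        d, h, w = D // 2, H // 2, W // 2
        g = grad.reshape(b, o, d, 2, h, 2, w, 2)
        self.weight.grad += np.einsum("bcdhw,bodihjwk->coijk", self._x, g,
                                      optimize=True)
        self.bias.grad += grad.sum(axis=(0, 2, 3, 4))
        return np.einsum("bodihjwk,coijk->bcdhw", g, self.weight.value,
                         optimize=True)


class BatchNorm3d(Layer):
    """Per-channel normalization with affine parameters.

    ``force_batch_stats`` makes evaluation use the statistics of the
    current input instead of the running averages (running averages are
    still only updated during training). With full-volume inference this
    amounts to instance normalization of the test image, which keeps the
    normalization consistent with the single-volume batches seen during
    randomized-contrast training.
    """

    def __init__(self, channels: int, momentum: float = 0.1,
                 eps: float = 1e-5, name: str = "bn"):
        self.gamma = Param(np.ones(channels), f"{name}.gamma")
        self.beta = Param(np.zeros(channels), f"{name}.beta")
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps
        self.force_batch_stats = False
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train):
        axes = (0, 2, 3, 4)
        shape = (1, -1, 1, 1, 1)
        if train or self.force_batch_stats:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            if train:
                self.running_mean = ((1 - self.momentum) * self.running_mean
                                     + self.momentum * mean)
                self.running_var = ((1 - self.momentum) * self.running_var
                                    + self.momentum * var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(shape)) * inv.reshape(shape)
        if train:
            self._cache = (xhat, inv, x.shape)
        return self.gamma.value.reshape(shape) * xhat + \
            self.beta.value.reshape(shape)

    def backward(self, grad):
        xhat, inv, xshape = self._cache
        axes = (0, 2, 3, 4)
        shape = (1, -1, 1, 1, 1)
        n = grad.size / grad.shape[1]
        self.gamma.grad += (grad * xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        g = self.gamma.value.reshape(shape)
        dxhat = grad * g
        return (inv.reshape(shape) / n) * (
            n * dxhat - dxhat.sum(axis=axes).reshape(shape)
            - xhat * (dxhat * xhat).sum(axis=axes).reshape(shape))


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Dropout(Layer):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, p: float, rng: np.random.Generator):
        self.p = p
        self.rng = rng
        self._mask = None

    def forward(self, x, train):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = ((self.rng.random(x.shape) < keep) / keep).astype(DTYPE)
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


class MaxPool3d(Layer):
    """2x2x2 max pooling, stride 2."""

    def forward(self, x, train):
        b, c, d, h, w = x.shape
        xr = x.reshape(b, c, d // 2, 2, h // 2, 2, w // 2, 2)
        xr = xr.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(
            b, c, d // 2, h // 2, w // 2, 8)
        self._arg = xr.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(xr, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, grad):
        b, c, d, h, w = self._shape
        gr = np.zeros((b, c, d // 2, h // 2, w // 2, 8))
        np.put_along_axis(gr, self._arg[..., None], grad[..., None], axis=-1)
        gr = gr.reshape(b, c, d // 2, h // 2, w // 2, 2, 2, 2)
        return gr.transpose(0, 1, 2, 5, 3, 6, 4, 7).reshape(b, c, d, h, w)


class Upsample3d(Layer):
    """2x nearest-neighbour upsampling; backward is 2x sum pooling."""

    def forward(self, x, train):
        return x.repeat(2, axis=2).repeat(2, axis=3).repeat(2, axis=4)

    def backward(self, grad):
        b, c, D, H, W = grad.shape
        return grad.reshape(b, c, D // 2, 2, H // 2, 2, W // 2, 2).sum(
            axis=(3, 5, 7))


def softmax_channels(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_backward(probs: np.ndarray, dprobs: np.ndarray) -> np.ndarray:
    dot = (dprobs * probs).sum(axis=1, keepdims=True)
    return probs * (dprobs - dot)


def soft_dice_loss(probs: np.ndarray, one_hot: np.ndarray,
                   return_grad: bool = False):
    """Average soft-dice loss over classes.

    Per class c the term is ``1 - 2 sum(p_c y_c) / (sum p_c^2 + sum y_c^2)``
    with sums over all voxels (and batch items); the loss is the mean over
    classes and lies in [0, 1]. A class empty in both the prediction and the
    target contributes 0 (the 0/0 convention).
    """
    if probs.shape != one_hot.shape:
        raise ValueError("prediction and target shapes differ")
    axes = tuple(i for i in range(probs.ndim) if i != 1)
    inter = (probs * one_hot).sum(axis=axes)
    denom = (probs ** 2).sum(axis=axes) + (one_hot ** 2).sum(axis=axes)
    n_classes = probs.shape[1]
    nonzero = denom > 0
    terms = np.zeros(n_classes)
    terms[nonzero] = 1.0 - 2.0 * inter[nonzero] / denom[nonzero]
    loss = float(terms.mean())
    if not return_grad:
        return loss
    grad = np.zeros_like(probs)
    shape = [1] * probs.ndim
    shape[1] = n_classes
    d = np.where(nonzero, denom, 1.0).reshape(shape)
    s = inter.reshape(shape)
    nz = nonzero.reshape(shape)
    grad = np.where(nz, 2.0 * (2.0 * s * probs - one_hot * d) /
                    (n_classes * d ** 2), 0.0)
    return loss, grad


@dataclass
class Adam:
    """Adam optimizer over a parameter list."""

    params: Sequence[Param]
    lr: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    t: int = 0
    _m: list = field(default_factory=list)
    _v: list = field(default_factory=list)

    def __post_init__(self):
        self._m = [np.zeros_like(p.value) for p in self.params]
        self._v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):
        self.t += 1
        b1t = 1 - self.beta1 ** self.t
        b2t = 1 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if not p.trainable:
                continue
            m *= self.beta1
            m += (1 - self.beta1) * p.grad
            v *= self.beta2
            v += (1 - self.beta2) * p.grad ** 2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
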