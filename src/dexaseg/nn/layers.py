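"""Minimal NumPy neural-network layers with explicit backpropagation.

All tensors are NCHW float32. Each layer caches what its backward pass
needs only when ``train=True`` is passed to ``forward``, so large
evaluation-only forwards stay memory-lean. Gradients accumulate into
``Parameter.grad``; an optimizer reads/zeroes them.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Parameter",
    "Layer",
    "Conv2d",
    "ConvTranspose2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2d",
    "softmax_channels",
    "softmax_backward",
]


class Parameter:
    """A trainable array plus its gradient accumulator."""

    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = ""):
        self.data = np.ascontiguousarray(data)
        self.grad = np.zeros_like(self.data)
        self.name = name

    def astype(self, dtype) -> None:
        """Cast in place (float64 casts support finite-difference checks)."""
        self.data = self.data.astype(dtype)
        self.grad = self.grad.astype(dtype)

    @property
    def shape(self):
        return self.data.shape

    @property
    def size(self):
        return self.data.size


class Layer:
    """Base class: parameter iteration and train/eval bookkeeping."""

    def parameters(self) -> list[Parameter]:
        out = []
        for v in vars(self).values():
            if isinstance(v, Parameter):
                out.append(v)
            elif isinstance(v, Layer):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Layer):
                        out.extend(item.parameters())
        return out

    def modules(self):
        """Yield this layer and every sub-layer, depth-first."""
        yield self
        for v in vars(self).values():
            if isinstance(v, Layer):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Layer):
                        yield from item.modules()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def he_normal(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    """He initialization: zero-mean normal with variance 2/fan_in."""
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Conv2d(Layer):
    """2-D convolution with 'same' zero padding (kernel 1 or 3 used here).

    Implemented as a sum of kernel-offset matmuls (tensordot per tap);
    this keeps peak memory at one input copy instead of an im2col buffer.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        if in_ch <= 0 or out_ch <= 0:
            raise ValueError("channel counts must be positive")
        if kernel % 2 != 1:
            raise ValueError("Conv2d supports odd kernels only")
        self.in_ch = in_ch
        self.out_ch = out_ch
        self.kernel = kernel
        fan_in = in_ch * kernel * kernel
        self.weight = Parameter(he_normal(rng, (out_ch, in_ch, kernel, kernel), fan_in), "conv.weight")
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32), "conv.bias")
        self._xpad = None

    def forward(self, x, train=False):
        k = self.kernel
        p = k // 2
        n, c, h, w = x.shape
        dtype = np.result_type(x.dtype, self.weight.data.dtype)
        if p:
            xpad = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=dtype)
            xpad[:, :, p:-p, p:-p] = x
        else:
            xpad = np.ascontiguousarray(x, dtype=dtype)
        y = np.empty((n, self.out_ch, h, w), dtype=dtype)
        y[:] = self.bias.data[None, :, None, None]
        W = self.weight.data
        for i in range(k):
            for j in range(k):
                # (O,C) x (N,C,H,W) -> (O,N,H,W)
                contrib = np.tensordot(W[:, :, i, j], xpad[:, :, i : i + h, j : j + w], axes=([1], [1]))
                y += contrib.transpose(1, 0, 2, 3)
        if train:
            self._xpad = xpad
            self._hw = (h, w)
        return y

    def backward(self, dy):
        k = self.kernel
        p = k // 2
        h, w = self._hw
        xpad = self._xpad
        W = self.weight.data
        self.bias.grad += dy.sum(axis=(0, 2, 3))
        dxpad = np.zeros_like(xpad)
        for i in range(k):
            for j in range(k):
                xs = xpad[:, :, i : i + h, j : j + w]
                # dW: (O,C) from (N,O,H,W) x (N,C,H,W)
                self.weight.grad[:, :, i, j] += np.tensordot(dy, xs, axes=([0, 2, 3], [0, 2, 3]))
                # dx: (C,O) x (N,O,H,W) -> (C,N,H,W)
                dxs = np.tensordot(W[:, :, i, j], dy, axes=([0], [1]))
                dxpad[:, :, i : i + h, j : j + w] += dxs.transpose(1, 0, 2, 3)
        self._xpad = None
        if p:
            return dxpad[:, :, p:-p, p:-p]
        return dxpad


class ConvTranspose2d(Layer):
    """2x2 stride-2 transposed convolution (exact 2x upsampling).

    Kernel equals stride, so output taps never overlap and each output
    pixel is a single linear map of one input pixel.
    """

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        if in_ch <= 0 or out_ch <= 0:
            raise ValueError("channel counts must be positive")
        self.in_ch = in_ch
        self.out_ch = out_ch
        self.kernel = 2
        self.stride = 2
        fan_in = in_ch * 4
        self.weight = Parameter(he_normal(rng, (in_ch, out_ch, 2, 2), fan_in), "tconv.weight")
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32), "tconv.bias")
        self._x = None

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        dtype = np.result_type(x.dtype, self.weight.data.dtype)
        y = np.empty((n, self.out_ch, 2 * h, 2 * w), dtype=dtype)
        W = self.weight.data
        for i in range(2):
            for j in range(2):
                contrib = np.tensordot(W[:, :, i, j], x, axes=([0], [1]))  # (O,N,H,W)
                y[:, :, i::2, j::2] = contrib.transpose(1, 0, 2, 3)
        y += self.bias.data[None, :, None, None]
        if train:
            self._x = x
        return y

    def backward(self, dy):
        x = self._x
        W = self.weight.data
        self.bias.grad += dy.sum(axis=(0, 2, 3))
        dx = np.zeros_like(x)
        for i in range(2):
            for j in range(2):
                dyij = dy[:, :, i::2, j::2]
                self.weight.grad[:, :, i, j] += np.tensordot(x, dyij, axes=([0, 2, 3], [0, 2, 3]))
                dxi = np.tensordot(W[:, :, i, j], dyij, axes=([1], [1]))  # (I,N,H,W)
                dx += dxi.transpose(1, 0, 2, 3)
        self._x = None
        return dx


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics.

    gamma=1, beta=0 at init; running stats updated with momentum 0.1 in
    training mode and used verbatim in evaluation mode.
    """

    def __init__(self, n_ch: int, eps: float = 1e-5, momentum: float = 0.1):
        self.n_ch = n_ch
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(n_ch, dtype=np.float32), "bn.gamma")
        self.beta = Parameter(np.zeros(n_ch, dtype=np.float32), "bn.beta")
        self.running_mean = np.zeros(n_ch, dtype=np.float32)
        self.running_var = np.ones(n_ch, dtype=np.float32)
        self._cache = None

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mean
            self.running_var = (1 - m) * self.running_var + m * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        y = self.gamma.data[None, :, None, None] * xhat + self.beta.data[None, :, None, None]
        if train:
            self._cache = (xhat, inv)
        return y.astype(np.result_type(x.dtype, self.gamma.data.dtype), copy=False)

    def backward(self, dy):
        xhat, inv = self._cache
        self._cache = None
        n = dy.shape[0] * dy.shape[2] * dy.shape[3]
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        g = self.gamma.data[None, :, None, None]
        dxhat = dy * g
        # standard batchnorm backward, folded per channel
        s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        dx = (dxhat - s1 / n - xhat * s2 / n) * inv[None, :, None, None]
        return dx.astype(dy.dtype, copy=False)


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x, train=False):
        y = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, dy):
        dx = dy * self._mask
        self._mask = None
        return dx


class MaxPool2d(Layer):
    """2x2 max pooling with stride 2 (even input dims required)."""

    def __init__(self):
        self._cache = None

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("MaxPool2d requires even spatial dims")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        idx = xr.argmax(axis=-1)
        y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (idx, (n, c, h, w))
        return y

    def backward(self, dy):
        idx, (n, c, h, w) = self._cache
        self._cache = None
        dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=dy.dtype)
        np.put_along_axis(dxr, idx[..., None], dy[..., None], axis=-1)
        dx = dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)
        return dx


def softmax_channels(logits: np.ndarray) -> np.ndarray:
    """Numerically stable softmax over the channel axis of NCHW logits."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_backward(probs: np.ndarray, dprobs: np.ndarray) -> np.ndarray:
    """Gradient of loss w.r.t. logits given probs and dL/dprobs."""
    dot = (dprobs * probs).sum(axis=1, keepdims=True)
    return probs * (dprobs - dot)
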