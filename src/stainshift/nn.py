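"""Minimal numpy neural-network layers with explicit backpropagation.

Everything the domain-adversarial trainer needs — 2-D convolution,
batch normalization, max-pooling, dropout, dense layers, the gradient
reversal operation and softmax cross-entropy — implemented directly on
numpy arrays with hand-written backward passes.  Layers follow a small
contract:

* ``forward(x, train)`` caches whatever the backward pass needs;
* ``backward(grad)`` returns the gradient w.r.t. the input and fills
  ``self.grads`` (same keys as ``self.params``);
* parameters live in ``self.params`` (dict of arrays) so an optimizer can
  update them in place.

Images are channel-last ``(N, H, W, C)`` float arrays.  All randomness
(weight init, dropout masks) flows through explicitly passed
``numpy.random.Generator`` objects, which is what makes training runs
bit-reproducible.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer",
    "Conv2D",
    "BatchNorm",
    "ReLU",
    "MaxPool2",
    "Dropout",
    "Flatten",
    "Dense",
    "GradientReversal",
    "Sequential",
    "reverse_gradient",
    "softmax",
    "softmax_cross_entropy",
    "sgd_update",
]


def reverse_gradient(upstream: np.ndarray, lam: float) -> np.ndarray:
    """Backward contract of the gradient reversal layer.

    The forward pass is the identity; on the way back the incoming
    gradient is multiplied by ``-lam``, so the shared trunk descends the
    task loss while *ascending* the domain loss scaled by ``lam``.
    """
    return -lam * np.asarray(upstream)


class Layer:
    """Base layer: parameter-free identity."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad


class Dense(Layer):
    """Affine map ``x @ W + b`` with He-scaled Gaussian init."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 bias: bool = True) -> None:
        super().__init__()
        scale = np.sqrt(2.0 / n_in)
        self.params = {"W": rng.normal(0.0, scale, size=(n_in, n_out))}
        if bias:
            self.params["b"] = np.zeros(n_out)
        self._x: np.ndarray | None = None

    def forward(self, x, train=False):
        self._x = x
        out = x @ self.params["W"]
        if "b" in self.params:
            out = out + self.params["b"]
        return out

    def backward(self, grad):
        self.grads["W"] = self._x.T @ grad
        if "b" in self.params:
            self.grads["b"] = grad.sum(axis=0)
        return grad @ self.params["W"].T


class Conv2D(Layer):
    """3x3-style convolution via im2col, 'same' padding, optional stride."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 kernel: int = 3, stride: int = 1) -> None:
        super().__init__()
        self.kernel = kernel
        self.stride = stride
        scale = np.sqrt(2.0 / (kernel * kernel * n_in))
        self.params = {
            "W": rng.normal(0.0, scale, size=(kernel * kernel * n_in, n_out)),
            "b": np.zeros(n_out),
        }
        self.n_in, self.n_out = n_in, n_out

    def _pad(self) -> int:
        return (self.kernel - 1) // 2

    def forward(self, x, train=False):
        k, s, p = self.kernel, self.stride, self._pad()
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        # (N, oh*, ow*, C, k, k) windows, then stride and flatten to columns
        win = sliding_window_view(xp, (k, k), axis=(1, 2))[:, ::s, ::s]
        n, oh, ow = win.shape[:3]
        cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(n, oh, ow, k * k * self.n_in)
        self._cols, self._xshape = cols, x.shape
        return cols @ self.params["W"] + self.params["b"]

    def backward(self, grad):
        k, s, p = self.kernel, self.stride, self._pad()
        n, oh, ow, _ = grad.shape
        cols2d = self._cols.reshape(-1, self._cols.shape[-1])
        g2d = grad.reshape(-1, self.n_out)
        self.grads["W"] = cols2d.T @ g2d
        self.grads["b"] = g2d.sum(axis=0)
        dcols = (grad @ self.params["W"].T).reshape(n, oh, ow, k, k, self.n_in)
        _, h, w, _ = self._xshape
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, self.n_in))
        for i in range(k):
            for j in range(k):
                dxp[:, i : i + oh * s : s, j : j + ow * s : s] += dcols[:, :, :, i, j]
        return dxp[:, p : p + h, p : p + w]


class BatchNorm(Layer):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, n_ch: int, momentum: float = 0.9, eps: float = 1e-5) -> None:
        super().__init__()
        self.params = {"gamma": np.ones(n_ch), "beta": np.zeros(n_ch)}
        self.running_mean = np.zeros(n_ch)
        self.running_var = np.ones(n_ch)
        self.momentum, self.eps = momentum, eps

    def forward(self, x, train=False):
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._istd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean) * self._istd
        self._axes = axes
        self._m = x.size // x.shape[-1]
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, grad):
        axes, m = self._axes, self._m
        self.grads["gamma"] = (grad * self._xhat).sum(axis=axes)
        self.grads["beta"] = grad.sum(axis=axes)
        gx = grad * self.params["gamma"]
        return self._istd * (
            gx
            - gx.mean(axis=axes)
            - self._xhat * (gx * self._xhat).sum(axis=axes) / m
        )


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; gradient split evenly among tied maxima."""

    def forward(self, x, train=False):
        n, h, w, c = x.shape
        x4 = x.reshape(n, h // 2, 2, w // 2, 2, c)
        out = x4.max(axis=(2, 4))
        mask = x4 == out[:, :, None, :, None, :]
        self._mask = mask / mask.sum(axis=(2, 4), keepdims=True)
        self._shape = x.shape
        return out

    def backward(self, grad):
        g = self._mask * grad[:, :, None, :, None, :]
        return g.reshape(self._shape)


class Dropout(Layer):
    """Inverted dropout; mask randomness comes from the generator handed in
    at construction (so runs are reproducible and two models sharing a
    generator consume it identically)."""

    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        super().__init__()
        self.rate = rate
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class GradientReversal(Layer):
    """Identity forward; multiplies the backward gradient by ``-lam``.

    ``lam`` is mutable so the trainer can run the warmup schedule."""

    def __init__(self, lam: float = 1.0) -> None:
        super().__init__()
        self.lam = lam

    def backward(self, grad):
        return reverse_gradient(grad, self.lam)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]) -> None:
        super().__init__()
        self.layers = list(layers)

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def parameters(self) -> list[tuple[Layer, str]]:
        out = []
        for layer in self.layers:
            if isinstance(layer, Sequential):
                out.extend(layer.parameters())
            else:
                out.extend((layer, name) for name in layer.params)
        return out

    def n_parameters(self) -> int:
        return sum(layer.params[name].size for layer, name in self.parameters())

    def _batchnorms(self) -> list["BatchNorm"]:
        out = []
        for layer in self.layers:
            if isinstance(layer, Sequential):
                out.extend(layer._batchnorms())
            elif isinstance(layer, BatchNorm):
                out.append(layer)
        return out

    def state(self) -> list[np.ndarray]:
        arrays = [layer.params[name].copy() for layer, name in self.parameters()]
        for bn in self._batchnorms():
            arrays += [bn.running_mean.copy(), bn.running_var.copy()]
        return arrays

    def load_state(self, arrays: list[np.ndarray]) -> None:
        it = iter(arrays)
        for layer, name in self.parameters():
            layer.params[name] = next(it).copy()
        for bn in self._batchnorms():
            bn.running_mean = next(it).copy()
            bn.running_var = next(it).copy()


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and its gradient w.r.t. the logits.

    ``labels`` may be integer class indices or one-hot rows."""
    p = softmax(logits)
    n = logits.shape[0]
    labels = np.asarray(labels)
    if labels.ndim == 1:
        onehot = np.zeros_like(p)
        onehot[np.arange(n), labels.astype(int)] = 1.0
    else:
        onehot = labels
    loss = float(-(onehot * np.log(np.maximum(p, 1e-12))).sum() / n)
    return loss, (p - onehot) / n


def sgd_update(net: Sequential, lr: float) -> None:
    """Plain stochastic gradient descent: ``p <- p - lr * g`` in place."""
    if lr == 0.0:
        return
    for layer, name in net.parameters():
        layer.params[name] -= lr * layer.grads[name]
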