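"""Minimal feed-forward neural-network layers with explicit backpropagation.

Everything here operates on ``float`` numpy arrays in NCHW layout
(batch, channels, height, width).  Layers cache what their backward pass
needs during ``forward``; ``backward`` consumes the upstream gradient,
accumulates parameter gradients in-place and returns the gradient with
respect to the layer input.  There is no autograd graph — the network
classes chain the calls by hand, which keeps every gradient inspectable
and testable against finite differences.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Parameter",
    "Module",
    "Conv2d",
    "Linear",
    "ReLU",
    "Sigmoid",
    "MaxPool2",
    "Flatten",
    "Sequential",
    "he_init",
    "softmax",
    "softmax_cross_entropy",
]


def he_init(shape: tuple[int, ...], fan: int, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean Gaussian weights scaled by sqrt(2 / fan).

    ``fan`` is the number of input connections per output unit; for a
    convolution this is ``k*k*C_in`` (the full fan-in) or, under the
    alternative ``channels`` convention, just ``C_in``.
    """
    if fan < 1:
        raise ValueError(f"fan must be a positive integer, got {fan}")
    return rng.standard_normal(shape) * np.sqrt(2.0 / fan)


class Parameter:
    """A trainable array together with its accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.name = name

    def astype(self, dtype) -> None:
        self.value = self.value.astype(dtype)
        self.grad = np.zeros_like(self.value)


class Module:
    """Base class: a callable layer with parameters and a backward pass."""

    def parameters(self) -> list[Parameter]:
        return []

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def astype(self, dtype) -> "Module":
        for p in self.parameters():
            p.astype(dtype)
        return self

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


class Conv2d(Module):
    """3x3-style convolution, stride 1, symmetric zero padding.

    Implemented as im2col + matmul.  ``fan_mode`` selects the fan used by
    the He initializer: ``"full"`` uses k*k*C_in, ``"channels"`` uses C_in.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int = 3,
        padding: int = 1,
        rng: np.random.Generator | None = None,
        fan_mode: str = "full",
        name: str = "conv",
    ):
        if fan_mode not in ("full", "channels"):
            raise ValueError(f"unknown fan_mode {fan_mode!r}")
        rng = rng if rng is not None else np.random.default_rng(0)
        k = kernel_size
        fan = in_channels * k * k if fan_mode == "full" else in_channels
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = k
        self.padding = padding
        self.weight = Parameter(he_init((out_channels, in_channels, k, k), fan, rng), f"{name}.weight")
        self.bias = Parameter(np.zeros(out_channels), f"{name}.bias")
        self._cache = None

    def parameters(self) -> list[Parameter]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 4 or x.shape[1] != self.in_channels:
            raise ValueError(
                f"expected (N, {self.in_channels}, H, W) input, got shape {x.shape}"
            )
        n, c, h, w = x.shape
        k, p = self.kernel_size, self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        ho, wo = h + 2 * p - k + 1, w + 2 * p - k + 1
        # (N, C, Ho, Wo, k, k) view, then columns of length C*k*k
        win = sliding_window_view(xp, (k, k), axis=(2, 3))
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
        wmat = self.weight.value.reshape(self.out_channels, c * k * k)
        out = cols @ wmat.T + self.bias.value
        self._cache = (cols, x.shape)
        return out.reshape(n, ho, wo, self.out_channels).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, xshape = self._cache
        n, c, h, w = xshape
        k, p = self.kernel_size, self.padding
        _, _, ho, wo = dout.shape
        dmat = dout.transpose(0, 2, 3, 1).reshape(n * ho * wo, self.out_channels)
        self.weight.grad += (dmat.T @ cols).reshape(self.weight.value.shape)
        self.bias.grad += dmat.sum(axis=0)
        dcols = dmat @ self.weight.value.reshape(self.out_channels, c * k * k)
        dcols = dcols.reshape(n, ho, wo, c, k, k).transpose(0, 3, 4, 5, 1, 2)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=dout.dtype)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + ho, j : j + wo] += dcols[:, :, i, j]
        return dxp[:, :, p : p + h, p : p + w]


class Linear(Module):
    """Affine map on flattened inputs (N, d_in) -> (N, d_out)."""

    def __init__(
        self,
        in_features: int,
        out_features: int,
        rng: np.random.Generator | None = None,
        name: str = "fc",
    ):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.in_features = in_features
        self.out_features = out_features
        self.weight = Parameter(he_init((out_features, in_features), in_features, rng), f"{name}.weight")
        self.bias = Parameter(np.zeros(out_features), f"{name}.bias")
        self._x = None

    def parameters(self) -> list[Parameter]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 2 or x.shape[1] != self.in_features:
            raise ValueError(f"expected (N, {self.in_features}) input, got shape {x.shape}")
        self._x = x
        return x @ self.weight.value.T + self.bias.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.weight.grad += dout.T @ self._x
        self.bias.grad += dout.sum(axis=0)
        return dout @ self.weight.value


class ReLU(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, 0.0)


class Sigmoid(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = sigmoid(x)
        return self._y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._y * (1.0 - self._y)


def sigmoid(x: np.ndarray) -> np.ndarray:
    # numerically stable on both tails
    out = np.empty_like(x, dtype=np.result_type(x, np.float32))
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class MaxPool2(Module):
    """2x2 max pooling with stride 2; odd trailing rows/columns are dropped
    (output size floors), matching the usual pad-0 pooling convention."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        ho, wo = h // 2, w // 2
        xr = x[:, :, : 2 * ho, : 2 * wo].reshape(n, c, ho, 2, wo, 2)
        xr = xr.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, ho, wo, 4)
        self._idx = xr.argmax(axis=-1)
        self._inshape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._inshape
        ho, wo = h // 2, w // 2
        dxr = np.zeros((n, c, ho, wo, 4), dtype=dout.dtype)
        np.put_along_axis(dxr, self._idx[..., None], dout[..., None], axis=-1)
        dx = np.zeros((n, c, h, w), dtype=dout.dtype)
        dx[:, :, : 2 * ho, : 2 * wo] = (
            dxr.reshape(n, c, ho, wo, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, 2 * ho, 2 * wo)
        )
        return dx


class Flatten(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def parameters(self) -> list[Parameter]:
        return [p for layer in self.layers for p in layer.parameters()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax with max-logit subtraction for stability."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, onehot: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean softmax cross-entropy over a batch and its gradient.

    ``logits`` and ``onehot`` are (N, T); each label row must be one-hot.
    Returns ``(loss, dlogits)`` where ``dlogits = (softmax(a) - y) / N``.
    """
    logits = np.asarray(logits, dtype=float)
    onehot = np.asarray(onehot)
    if logits.shape != onehot.shape:
        raise ValueError(f"shape mismatch: logits {logits.shape} vs labels {onehot.shape}")
    rows_ok = np.all(np.isin(onehot, (0, 1))) and np.all(onehot.sum(axis=-1) == 1)
    if not rows_ok:
        raise ValueError("labels must be one-hot rows (exactly one 1, rest 0)")
    n = logits.shape[0]
    z = logits - logits.max(axis=-1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=-1, keepdims=True))
    loss = float(-(onehot * logp).sum() / n)
    dlogits = (np.exp(logp) - onehot) / n
    return loss, dlogits
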