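"""Per-channel sigmoid attention gating.

Each color channel of the spatially transformed face image is convolved
independently with its own single-input 3x3 kernel (padding 1), passed
through a sigmoid to yield a weight map in (0, 1), and the input is then
multiplied elementwise by its weight map:

    V' = V * sigmoid(conv(V))     (per channel)

Because informative facial regions (brows, eyes, mouth) differ in local
structure from background clutter, the gates can learn to down-weight
uninformative areas while passing face regions through.
"""

from __future__ import annotations

import numpy as np

from .nn import Conv2d, Module, sigmoid


def attention_weights(v: np.ndarray, kernels: np.ndarray, biases: np.ndarray) -> np.ndarray:
    """Functional gate computation on an (H, W, C) or (N, C, H, W) map.

    ``kernels`` is (C, 3, 3) — one unshared kernel per channel — and
    ``biases`` is (C,).  Returns sigmoid(conv(V)) with the same spatial
    size as the input.
    """
    kernels = np.asarray(kernels, dtype=float)
    biases = np.asarray(biases, dtype=float)
    channels_last = v.ndim == 3
    x = np.asarray(v, dtype=float)
    if channels_last:
        x = x.transpose(2, 0, 1)[None]
    c = x.shape[1]
    if kernels.shape != (c, 3, 3):
        raise ValueError(f"expected kernels of shape ({c}, 3, 3), got {kernels.shape}")
    out = np.empty_like(x)
    for ch in range(c):
        conv = Conv2d(1, 1, kernel_size=3, padding=1)
        conv.weight.value[...] = kernels[ch][None, None]
        conv.bias.value[...] = biases[ch]
        out[:, ch : ch + 1] = conv(x[:, ch : ch + 1])
    a = sigmoid(out)
    return a[0].transpose(1, 2, 0) if channels_last else a


def apply_attention(v: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Elementwise product of a feature map and its attention weights."""
    v = np.asarray(v, dtype=float)
    a = np.asarray(a, dtype=float)
    if v.shape != a.shape:
        raise ValueError(f"shape mismatch: map {v.shape} vs weights {a.shape}")
    return v * a


class ChannelAttention(Module):
    """Trainable gating module over an (N, C, H, W) map.

    One independent 1-in/1-out 3x3 convolution per channel (optionally a
    single shared kernel), sigmoid activation, elementwise product.  The
    most recent weight maps are kept in ``last_weights`` so they can be
    dumped as grayscale images for inspection.
    """

    def __init__(
        self,
        channels: int = 3,
        rng: np.random.Generator | None = None,
        fan_mode: str = "full",
        share_weights: bool = False,
    ):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.channels = channels
        self.share_weights = share_weights
        n_convs = 1 if share_weights else channels
        self.convs = [
            Conv2d(1, 1, kernel_size=3, padding=1, rng=rng, fan_mode=fan_mode, name=f"att.conv{i}")
            for i in range(n_convs)
        ]
        self.last_weights: np.ndarray | None = None

    def parameters(self):
        return [p for conv in self.convs for p in conv.parameters()]

    def _conv(self, ch: int) -> Conv2d:
        return self.convs[0] if self.share_weights else self.convs[ch]

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 4 or x.shape[1] != self.channels:
            raise ValueError(f"expected (N, {self.channels}, H, W) input, got {x.shape}")
        self._x = x
        n, c, h, w = x.shape
        if self.share_weights:
            # fold channels into the batch so one conv call caches everything
            a = sigmoid(self.convs[0](x.reshape(n * c, 1, h, w)).reshape(n, c, h, w))
        else:
            a = np.empty_like(x)
            for ch in range(c):
                a[:, ch : ch + 1] = sigmoid(self.convs[ch](x[:, ch : ch + 1]))
        self.last_weights = a
        return x * a

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, a = self._x, self.last_weights
        n, c, h, w = x.shape
        dx = dout * a
        dz = dout * x * a * (1.0 - a)
        if self.share_weights:
            dx += self.convs[0].backward(dz.reshape(n * c, 1, h, w)).reshape(n, c, h, w)
        else:
            for ch in range(c):
                dx[:, ch : ch + 1] += self.convs[ch].backward(dz[:, ch : ch + 1])
        return dx


def save_attention_maps(attention: ChannelAttention, out_prefix) -> list:
    """Dump the most recent weight maps as grayscale PNGs, one per item
    and channel, for qualitative inspection of what the gates suppress."""
    from pathlib import Path

    from PIL import Image

    if attention.last_weights is None:
        raise ValueError("no attention maps recorded: run a forward pass first")
    channel_names = "rgb" if attention.channels == 3 else [str(i) for i in range(attention.channels)]
    written = []
    for b in range(attention.last_weights.shape[0]):
        for ch, name in enumerate(channel_names):
            path = Path(f"{out_prefix}_{b:03d}_{name}.png")
            arr = (attention.last_weights[b, ch] * 255.0 + 0.5).astype(np.uint8)
            Image.fromarray(arr, "L").save(path)
            written.append(path)
    return written
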