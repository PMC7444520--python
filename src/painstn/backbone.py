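"""CNN feature extractor and 4-way softmax classification head.

The backbone is a stack of (3x3 conv -> ReLU -> 2x2 max-pool) blocks;
at the canonical 192x192x3 input the filter schedule is
(64, 64, 128, 128, 256, 256), which reduces the spatial size
192 -> 96 -> 48 -> 24 -> 12 -> 6 -> 3 and yields 3x3x256 feature maps.
A single fully connected layer maps the flattened 2304 features to one
logit per pain level; training minimizes softmax cross-entropy and
prediction takes the arg-max logit (ties resolved to the lowest level).

For reduced-resolution clones (inputs of size 3 * 2**k with k < 6) the
schedule is truncated to the first k entries, or replaced by an explicit
``filters`` tuple.
"""

from __future__ import annotations

import numpy as np

from .nn import (
    Conv2d,
    Flatten,
    Linear,
    MaxPool2,
    Module,
    ReLU,
    Sequential,
    softmax_cross_entropy,
)
from .stn import _n_halvings

CANONICAL_FILTERS = (64, 64, 128, 128, 256, 256)
N_LEVELS = 4


class Backbone(Module):
    """Convolutional feature extractor ending in 3x3 spatial maps."""

    def __init__(
        self,
        image_size: int = 192,
        in_channels: int = 3,
        filters: tuple[int, ...] | None = None,
        rng: np.random.Generator | None = None,
        fan_mode: str = "full",
    ):
        rng = rng if rng is not None else np.random.default_rng(0)
        n_blocks = _n_halvings(image_size)
        if filters is None:
            filters = CANONICAL_FILTERS[:n_blocks]
        if len(filters) != n_blocks:
            raise ValueError(
                f"{n_blocks} blocks needed to reduce {image_size} to 3, got {len(filters)} filter counts"
            )
        self.image_size = image_size
        self.in_channels = in_channels
        self.filters = tuple(filters)
        layers: list[Module] = []
        ch = in_channels
        for b, f in enumerate(filters):
            layers += [Conv2d(ch, f, rng=rng, fan_mode=fan_mode, name=f"cnn.conv{b}"), ReLU(), MaxPool2()]
            ch = f
        self.body = Sequential(*layers)
        self.out_channels = ch
        self.feature_dim = 3 * 3 * ch

    def parameters(self):
        return self.body.parameters()

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 4 or x.shape[1] != self.in_channels or x.shape[2] != self.image_size or x.shape[3] != self.image_size:
            raise ValueError(
                f"expected (N, {self.in_channels}, {self.image_size}, {self.image_size}) input, got {x.shape}"
            )
        return self.body(x)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return self.body.backward(dout)


class ClassifierHead(Module):
    """Flatten -> FC to one logit per pain level."""

    def __init__(self, feature_dim: int, n_levels: int = N_LEVELS, rng: np.random.Generator | None = None):
        self.flatten = Flatten()
        self.fc = Linear(feature_dim, n_levels, rng=rng, name="head.fc")

    def parameters(self):
        return self.fc.parameters()

    def forward(self, features: np.ndarray) -> np.ndarray:
        return self.fc(self.flatten(features))

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        return self.flatten.backward(self.fc.backward(dlogits))


def cnn_features(v: np.ndarray, backbone: Backbone) -> np.ndarray:
    """Extract features from one (H, W, C) attentional face image."""
    x = np.asarray(v, dtype=float).transpose(2, 0, 1)[None]
    return backbone(x)[0].transpose(1, 2, 0)


def classify(features: np.ndarray, head: ClassifierHead) -> np.ndarray:
    """Logit vector (length 4) for one 3x3xC feature map."""
    x = np.asarray(features, dtype=float).transpose(2, 0, 1)[None]
    return head(x)[0]


def softmax_loss(logits: np.ndarray, onehot: np.ndarray) -> float:
    """Softmax cross-entropy of one logit vector against a one-hot label."""
    loss, _ = softmax_cross_entropy(np.atleast_2d(logits), np.atleast_2d(onehot))
    return loss


def predict(logits: np.ndarray) -> np.ndarray:
    """Arg-max pain level(s); exact ties resolve to the lowest level index."""
    logits = np.asarray(logits, dtype=float)
    return np.argmax(logits, axis=-1)


def one_hot(levels: np.ndarray, n_levels: int = N_LEVELS) -> np.ndarray:
    levels = np.asarray(levels, dtype=int)
    if levels.min() < 0 or levels.max() >= n_levels:
        raise ValueError(f"levels must lie in [0, {n_levels})")
    return np.eye(n_levels)[levels]
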