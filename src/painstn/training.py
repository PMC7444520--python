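"""Training loop: SGD with classical momentum, per-epoch shuffling,
dev-set model selection and a divergence guard.

Defaults follow the reference training recipe: learning rate 1e-4,
momentum 0.9, He initialization of all conv/FC weights.  Mini-batches
are re-drawn randomly every epoch; after each epoch the development
split is scored and the parameter snapshot with the best dev accuracy
is retained.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .backbone import one_hot
from .network import PainNet
from .nn import Parameter, he_init  # noqa: F401  (he_init re-exported here)

__all__ = ["ModeConfig", "TrainState", "SGDMomentum", "train", "he_init"]

MODE_NAMES = {
    (False, False): "no-stn-no-att",
    (True, False): "stn-no-att",
    (False, True): "no-stn-att",
    (True, True): "stn-att",
}


@dataclass
class ModeConfig:
    """Ablation switches plus optimizer settings."""

    use_stn: bool = True
    use_attention: bool = True
    learning_rate: float = 1e-4
    momentum: float = 0.9
    batch_size: int = 64
    max_epochs: int = 50
    seed: int = 0
    image_size: int = 192
    loc_filters: int = 16
    loc_lr_scale: float = 1.0
    loc_head_damp: float = 0.0
    stn_identity_anchor: float = 0.0
    backbone_filters: tuple[int, ...] | None = None
    fan_mode: str = "full"
    identity_init: bool = True
    dtype: str = "float64"

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not (0.0 <= self.momentum < 1.0):
            raise ValueError("momentum must lie in [0, 1)")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be >= 1")
        if self.loc_lr_scale <= 0:
            raise ValueError("loc_lr_scale must be positive")

    @property
    def mode_name(self) -> str:
        return MODE_NAMES[(self.use_stn, self.use_attention)]

    def build_net(self) -> PainNet:
        return PainNet(
            image_size=self.image_size,
            use_stn=self.use_stn,
            use_attention=self.use_attention,
            loc_filters=self.loc_filters,
            backbone_filters=self.backbone_filters,
            fan_mode=self.fan_mode,
            identity_init=self.identity_init,
            loc_head_damp=self.loc_head_damp,
            stn_identity_anchor=self.stn_identity_anchor,
            seed=self.seed,
            dtype=np.dtype(self.dtype).type,
        )

    @classmethod
    def from_dict(cls, d: dict) -> "ModeConfig":
        d = dict(d)
        if d.get("backbone_filters") is not None:
            d["backbone_filters"] = tuple(d["backbone_filters"])
        return cls(**d)


class SGDMomentum:
    """Classical (heavy-ball) momentum: v <- beta*v - alpha*g; w <- w + v.

    ``param_scales`` optionally multiplies the learning rate per parameter
    (used to damp the localization network, whose transform parameters
    destroy the image — and their own gradient signal — if they overshoot).
    """

    def __init__(
        self,
        params: list[Parameter],
        learning_rate: float,
        momentum: float = 0.9,
        param_scales: list[float] | None = None,
    ):
        self.params = params
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.buffers = [np.zeros_like(p.value) for p in params]
        self.param_scales = param_scales if param_scales is not None else [1.0] * len(params)
        if len(self.param_scales) != len(params):
            raise ValueError("param_scales length must match params")

    def step(self) -> None:
        for p, v, s in zip(self.params, self.buffers, self.param_scales):
            if p.grad.shape != p.value.shape:
                raise ValueError(f"gradient shape mismatch for {p.name}")
            v *= self.momentum
            v -= (self.learning_rate * s) * p.grad
            p.value += v


@dataclass
class TrainState:
    """Outcome of a training run."""

    net: PainNet
    config: ModeConfig
    history: list[dict] = field(default_factory=list)
    best_dev_accuracy: float = -1.0
    best_epoch: int = -1
    best_state: list[np.ndarray] | None = None

    def restore_best(self) -> None:
        if self.best_state is not None:
            self.net.set_state(self.best_state)

    def save_history(self, path) -> None:
        with open(path, "w") as fh:
            for rec in self.history:
                fh.write(json.dumps(rec) + "\n")


def _accuracy(net: PainNet, images: np.ndarray, levels: np.ndarray, batch_size: int) -> float:
    correct = 0
    for start in range(0, len(images), batch_size):
        xb = images[start : start + batch_size]
        correct += int((net.predict(xb) == levels[start : start + batch_size]).sum())
    return 100.0 * correct / len(images)


def train(
    train_data: tuple[np.ndarray, np.ndarray],
    dev_data: tuple[np.ndarray, np.ndarray],
    config: ModeConfig,
    net: PainNet | None = None,
    verbose: bool = False,
) -> TrainState:
    """Train a PainNet on (images, levels) arrays.

    Images are channels-last (N, H, W, 3) in [0, 1]; they are moved to
    NCHW internally.  Returns a TrainState holding the per-epoch history
    and the parameter snapshot with the best dev accuracy.  Fully
    deterministic given ``config.seed``.
    """
    x_tr, y_tr = train_data
    x_dev, y_dev = dev_data
    if len(x_tr) == 0 or len(x_dev) == 0:
        raise ValueError("training and development splits must be non-empty")
    dtype = np.dtype(config.dtype).type
    x_tr = np.ascontiguousarray(np.asarray(x_tr, dtype=dtype).transpose(0, 3, 1, 2))
    x_dev = np.ascontiguousarray(np.asarray(x_dev, dtype=dtype).transpose(0, 3, 1, 2))
    y_tr = np.asarray(y_tr, dtype=int)
    y_dev = np.asarray(y_dev, dtype=int)
    onehot_tr = one_hot(y_tr).astype(dtype)

    if net is None:
        net = config.build_net()
    loc_params = set(map(id, net.stn.parameters())) if net.stn is not None else set()
    scales = [config.loc_lr_scale if id(p) in loc_params else 1.0 for p in net.parameters()]
    opt = SGDMomentum(net.parameters(), config.learning_rate, config.momentum, param_scales=scales)
    rng = np.random.default_rng(config.seed)
    state = TrainState(net=net, config=config)

    for epoch in range(config.max_epochs):
        order = rng.permutation(len(x_tr))
        epoch_loss, n_correct = 0.0, 0
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            net.zero_grad()
            loss, logits = net.loss_and_grad(x_tr[idx], onehot_tr[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged: non-finite loss at epoch {epoch}, batch offset {start}"
                )
            opt.step()
            epoch_loss += loss * len(idx)
            n_correct += int((np.argmax(logits, axis=-1) == y_tr[idx]).sum())
        dev_acc = _accuracy(net, x_dev, y_dev, config.batch_size)
        rec = {
            "epoch": epoch,
            "mode": config.mode_name,
            "train_loss": epoch_loss / len(order),
            "train_accuracy": 100.0 * n_correct / len(order),
            "dev_accuracy": dev_acc,
        }
        state.history.append(rec)
        if verbose:
            print(json.dumps(rec))
        if dev_acc > state.best_dev_accuracy:
            state.best_dev_accuracy = dev_acc
            state.best_epoch = epoch
            state.best_state = net.get_state()
    state.restore_best()
    return state


def load_config(path) -> ModeConfig:
    """Read a ModeConfig from a YAML or JSON file."""
    import yaml

    payload = yaml.safe_load(Path(path).read_text())
    return ModeConfig.from_dict(payload)
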