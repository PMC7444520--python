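"""End-to-end pain network: optional STN -> optional attention -> CNN ->
4-way softmax head, with hand-chained backpropagation.

The two ablation switches only add or remove the STN and attention
stages; the backbone and head are constructed identically in every mode,
so parameter counts of the shared stages agree across modes.
"""

from __future__ import annotations

import json

import numpy as np

from .attention import ChannelAttention
from .backbone import Backbone, ClassifierHead, N_LEVELS
from .nn import Module, Parameter, softmax, softmax_cross_entropy
from .stn import SpatialTransformer


class PainNet(Module):
    """Composable four-level pain-intensity classifier network."""

    def __init__(
        self,
        image_size: int = 192,
        use_stn: bool = True,
        use_attention: bool = True,
        loc_filters: int = 16,
        backbone_filters: tuple[int, ...] | None = None,
        fan_mode: str = "full",
        identity_init: bool = True,
        loc_head_damp: float = 0.0,
        stn_identity_anchor: float = 0.0,
        seed: int = 0,
        dtype=np.float64,
    ):
        rng = np.random.default_rng(seed)
        self.config = {
            "image_size": image_size,
            "use_stn": use_stn,
            "use_attention": use_attention,
            "loc_filters": loc_filters,
            "backbone_filters": list(backbone_filters) if backbone_filters else None,
            "fan_mode": fan_mode,
            "identity_init": identity_init,
            "loc_head_damp": loc_head_damp,
            "stn_identity_anchor": stn_identity_anchor,
            "seed": seed,
        }
        self.image_size = image_size
        self.use_stn = use_stn
        self.use_attention = use_attention
        self.dtype = dtype
        # stage construction order is fixed so shared stages draw the same
        # initial weights regardless of which optional stages exist
        backbone_rng = np.random.default_rng(rng.integers(2**31))
        stn_rng = np.random.default_rng(rng.integers(2**31))
        att_rng = np.random.default_rng(rng.integers(2**31))
        self.backbone = Backbone(image_size, 3, backbone_filters, rng=backbone_rng, fan_mode=fan_mode)
        self.head = ClassifierHead(self.backbone.feature_dim, N_LEVELS, rng=backbone_rng)
        self.stn = (
            SpatialTransformer(
                image_size, 3, loc_filters, rng=stn_rng, fan_mode=fan_mode,
                identity_init=identity_init, head_damp=loc_head_damp,
                identity_anchor=stn_identity_anchor,
            )
            if use_stn
            else None
        )
        self.attention = ChannelAttention(3, rng=att_rng, fan_mode=fan_mode) if use_attention else None
        self.astype(dtype)

    # -- stage bookkeeping -------------------------------------------------
    def stages(self) -> dict[str, Module]:
        out = {"backbone": self.backbone, "head": self.head}
        if self.stn is not None:
            out["stn"] = self.stn
        if self.attention is not None:
            out["attention"] = self.attention
        return out

    def parameters(self) -> list[Parameter]:
        return [p for stage in self.stages().values() for p in stage.parameters()]

    def stage_parameter_counts(self) -> dict[str, int]:
        return {name: sum(p.value.size for p in s.parameters()) for name, s in self.stages().items()}

    # -- forward / backward ------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        """Logits (N, 4) from an (N, 3, H, W) batch in [0, 1]."""
        x = np.asarray(x, dtype=self.dtype)
        v = self.stn(x) if self.stn is not None else x
        v = self.attention(v) if self.attention is not None else v
        return self.head(self.backbone(v))

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        d = self.backbone.backward(self.head.backward(dlogits))
        if self.attention is not None:
            d = self.attention.backward(d)
        if self.stn is not None:
            d = self.stn.backward(d)
        return d

    def loss_and_grad(self, x: np.ndarray, onehot: np.ndarray) -> tuple[float, np.ndarray]:
        """Mean cross-entropy on a batch; accumulates parameter gradients."""
        logits = self.forward(x)
        loss, dlogits = softmax_cross_entropy(logits, onehot)
        self.backward(dlogits.astype(self.dtype))
        self._last_logits = logits
        return loss, logits

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.argmax(self.forward(x), axis=-1)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x))

    # -- parameter snapshots / checkpoints ---------------------------------
    def get_state(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.parameters()]

    def set_state(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError(f"state has {len(state)} arrays, network has {len(params)} parameters")
        for p, v in zip(params, state):
            if p.value.shape != v.shape:
                raise ValueError(f"shape mismatch for {p.name}: {p.value.shape} vs {v.shape}")
            p.value[...] = v

    def save(self, path) -> None:
        """Write a single-archive checkpoint (parameters + config)."""
        arrays = {f"param_{i:04d}": p.value for i, p in enumerate(self.parameters())}
        meta = json.dumps({"format_version": 1, "config": self.config})
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path, dtype=np.float64) -> "PainNet":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            if meta.get("format_version") != 1:
                raise ValueError(f"unsupported checkpoint format: {meta.get('format_version')}")
            cfg = meta["config"]
            net = cls(
                image_size=cfg["image_size"],
                use_stn=cfg["use_stn"],
                use_attention=cfg["use_attention"],
                loc_filters=cfg["loc_filters"],
                backbone_filters=tuple(cfg["backbone_filters"]) if cfg["backbone_filters"] else None,
                fan_mode=cfg["fan_mode"],
                identity_init=cfg["identity_init"],
                loc_head_damp=cfg.get("loc_head_damp", 0.0),
                stn_identity_anchor=cfg.get("stn_identity_anchor", 0.0),
                seed=cfg["seed"],
                dtype=dtype,
            )
            keys = sorted(k for k in data.files if k.startswith("param_"))
            net.set_state([data[k] for k in keys])
        return net
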