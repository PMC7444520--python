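"""Scikit-learn style estimator wrapping the full pipeline.

``PainLevelClassifier`` exposes fit/predict/predict_proba over image
arrays, composes with sklearn model selection, and surfaces the two
ablation switches (spatial transformer, attention gating) as estimator
parameters.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .evaluation import evaluate
from .training import ModeConfig, train


class PainLevelClassifier(ClassifierMixin, BaseEstimator):
    """Four-level pain-intensity classifier over face images.

    Parameters mirror the training recipe: SGD with momentum 0.9 and
    learning rate 1e-4 by default, He-initialized weights, dev-set model
    selection when a development split is supplied to :meth:`fit`.

    Parameters
    ----------
    use_stn : bool
        Include the spatial transformer stage (undoes affine nuisance).
    use_attention : bool
        Include per-channel sigmoid attention gating.
    image_size : int
        Side length of the square input; must be 3 * 2**k (192, 96, 48, 24...).
    backbone_filters : tuple of int, optional
        Conv filter counts per block; defaults to the canonical schedule
        (64, 64, 128, 128, 256, 256) truncated to the block count.
    random_state : int
        Root seed for initialization and batch shuffling.

    Attributes
    ----------
    net_ : PainNet
        The trained network (best dev snapshot when a dev split was given).
    history_ : list of dict
        Per-epoch training log (loss, train accuracy, dev accuracy).
    best_dev_accuracy_ : float
        Highest development-split accuracy observed.
    classes_ : ndarray
        The pain levels, ``[0 1 2 3]``.
    """

    def __init__(
        self,
        use_stn: bool = True,
        use_attention: bool = True,
        learning_rate: float = 1e-4,
        momentum: float = 0.9,
        batch_size: int = 64,
        max_epochs: int = 50,
        image_size: int = 192,
        loc_filters: int = 16,
        loc_lr_scale: float = 1.0,
        loc_head_damp: float = 0.0,
        stn_identity_anchor: float = 0.0,
        backbone_filters: tuple[int, ...] | None = None,
        fan_mode: str = "full",
        identity_init: bool = True,
        dtype: str = "float64",
        random_state: int = 0,
    ):
        self.use_stn = use_stn
        self.use_attention = use_attention
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.image_size = image_size
        self.loc_filters = loc_filters
        self.loc_lr_scale = loc_lr_scale
        self.loc_head_damp = loc_head_damp
        self.stn_identity_anchor = stn_identity_anchor
        self.backbone_filters = backbone_filters
        self.fan_mode = fan_mode
        self.identity_init = identity_init
        self.dtype = dtype
        self.random_state = random_state

    def _config(self) -> ModeConfig:
        return ModeConfig(
            use_stn=self.use_stn,
            use_attention=self.use_attention,
            learning_rate=self.learning_rate,
            momentum=self.momentum,
            batch_size=self.batch_size,
            max_epochs=self.max_epochs,
            seed=self.random_state,
            image_size=self.image_size,
            loc_filters=self.loc_filters,
            loc_lr_scale=self.loc_lr_scale,
            loc_head_damp=self.loc_head_damp,
            stn_identity_anchor=self.stn_identity_anchor,
            backbone_filters=self.backbone_filters,
            fan_mode=self.fan_mode,
            identity_init=self.identity_init,
            dtype=self.dtype,
        )

    def _validate_images(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        s = self.image_size
        if X.ndim != 4 or X.shape[1:] != (s, s, 3):
            raise ValueError(f"X must be (n, {s}, {s}, 3) channels-last images, got {X.shape}")
        return X

    def fit(self, X, y, X_dev=None, y_dev=None):
        """Train on (n, S, S, 3) images in [0, 1] with integer levels ``y``.

        When no development split is given, a fifth of the training data
        (last fifth, order-preserving) is held out for model selection.
        """
        X = self._validate_images(X)
        y = np.asarray(y, dtype=int)
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        if X_dev is None:
            cut = max(1, int(0.8 * len(X)))
            X, X_dev = X[:cut], X[cut:] if cut < len(X) else X[:cut]
            y, y_dev = y[:cut], y[cut:] if cut < len(y) else y[:cut]
        state = train((X, y), (np.asarray(X_dev, dtype=float), np.asarray(y_dev, dtype=int)), self._config())
        self.net_ = state.net
        self.history_ = state.history
        self.best_dev_accuracy_ = state.best_dev_accuracy
        self.best_epoch_ = state.best_epoch
        self.classes_ = np.arange(4)
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "net_")
        X = self._validate_images(X)
        out = []
        for start in range(0, len(X), self.batch_size):
            out.append(self.net_.forward(X[start : start + self.batch_size].transpose(0, 3, 1, 2)))
        return np.concatenate(out)

    def predict_proba(self, X) -> np.ndarray:
        from .nn import softmax

        return softmax(self.decision_function(X))

    def predict(self, X) -> np.ndarray:
        return np.argmax(self.decision_function(X), axis=-1)

    def evaluate(self, X, y, mode: str | None = None):
        """Metric report + confusion matrix on a labeled split."""
        check_is_fitted(self, "net_")
        label = mode if mode is not None else self._config().mode_name
        return evaluate(self.net_, self._validate_images(X), y, mode=label, batch_size=self.batch_size)
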