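"""Evaluation: confusion matrices, accuracy/precision/recall, level MSE,
and 2-D PCA projections of classifier features.

Metrics follow the conventions of the four-level pain-estimation
literature: percentages at one decimal, MSE as the mean squared
difference between predicted and true *level indices* (an ordinal error
measure — confusing level 0 with level 3 costs 9, with level 1 costs 1),
and precision defined as 0 for a level whose diagonal count is 0.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.metrics import confusion_matrix as _sk_confusion

N_LEVELS = 4


@dataclass(frozen=True)
class MetricReport:
    """Per-mode evaluation summary.  Percentages in 0-100."""

    mode: str
    accuracy: float
    precision: tuple[float, ...]
    recall: tuple[float, ...]
    mse: float
    n: int

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "MetricReport":
        d = json.loads(text)
        d["precision"] = tuple(d["precision"])
        d["recall"] = tuple(d["recall"])
        return cls(**d)


def confusion(preds, truths, n_levels: int = N_LEVELS) -> np.ndarray:
    """Count matrix with rows = true level, columns = predicted level."""
    preds = np.asarray(preds, dtype=int)
    truths = np.asarray(truths, dtype=int)
    if preds.shape != truths.shape:
        raise ValueError(f"length mismatch: {preds.shape} predictions vs {truths.shape} truths")
    for name, arr in (("predictions", preds), ("truths", truths)):
        if arr.size and (arr.min() < 0 or arr.max() >= n_levels):
            raise ValueError(f"{name} contain levels outside [0, {n_levels})")
    return _sk_confusion(truths, preds, labels=np.arange(n_levels))


def metrics_from_confusion(cm, mode: str = "") -> MetricReport:
    """Accuracy, per-level precision/recall (percent) and level MSE."""
    cm = np.asarray(cm)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError(f"confusion matrix must be square, got shape {cm.shape}")
    if np.any(cm < 0):
        raise ValueError("confusion matrix entries must be non-negative")
    total = cm.sum()
    if total == 0:
        raise ValueError("confusion matrix is empty")
    k = cm.shape[0]
    diag = np.diag(cm).astype(float)
    row = cm.sum(axis=1).astype(float)
    col = cm.sum(axis=0).astype(float)
    recall = tuple(100.0 * diag[i] / row[i] if row[i] > 0 else 0.0 for i in range(k))
    precision = tuple(100.0 * diag[j] / col[j] if col[j] > 0 else 0.0 for j in range(k))
    levels = np.arange(k)
    sq = (levels[:, None] - levels[None, :]) ** 2
    mse = float((cm * sq).sum() / total)
    return MetricReport(
        mode=mode,
        accuracy=float(100.0 * diag.sum() / total),
        precision=precision,
        recall=recall,
        mse=mse,
        n=int(total),
    )


def pca_project(features) -> np.ndarray:
    """Mean-centered projection of feature vectors onto the top-2 principal
    axes, with a deterministic sign convention (the largest-magnitude
    loading of each axis is positive)."""
    x = np.asarray(features, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3:
        raise ValueError("need at least 3 feature vectors of consistent dimension")
    if np.allclose(x, x[0]):
        raise ValueError("degenerate input: all feature vectors identical")
    pca = PCA(n_components=2, svd_solver="full")
    proj = pca.fit_transform(x)
    for i, axis in enumerate(pca.components_):
        j = np.argmax(np.abs(axis))
        if axis[j] < 0:
            proj[:, i] = -proj[:, i]
    return proj


def evaluate(net, images, levels, mode: str = "", batch_size: int = 32, with_features: bool = False):
    """Run a network over labeled images and aggregate metrics.

    ``images`` is (N, H, W, 3) channels-last in [0, 1]; ``levels`` are
    integer pain levels.  Returns ``(report, cm)`` or, with features, a
    third (N, 2) array of PCA-projected logits for scatter plots.
    """
    images = np.asarray(images, dtype=net.dtype if hasattr(net, "dtype") else float)
    levels = np.asarray(levels, dtype=int)
    if len(images) == 0:
        raise ValueError("cannot evaluate on an empty split")
    preds, feats = [], []
    for start in range(0, len(images), batch_size):
        x = images[start : start + batch_size].transpose(0, 3, 1, 2)
        logits = net.forward(x)
        preds.append(np.argmax(logits, axis=-1))
        if with_features:
            feats.append(logits)
    preds = np.concatenate(preds)
    cm = confusion(preds, levels)
    report = metrics_from_confusion(cm, mode=mode)
    if with_features:
        return report, cm, pca_project(np.concatenate(feats))
    return report, cm


def write_confusion_csv(path, cm) -> None:
    labels = [f"level{i}" for i in range(np.asarray(cm).shape[0])]
    pd.DataFrame(cm, index=labels, columns=labels).to_csv(path, index_label="true\\pred")


def read_confusion_csv(path) -> np.ndarray:
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(dtype=int)


def write_scatter_csv(path, coords, levels) -> None:
    pd.DataFrame({"x": coords[:, 0], "y": coords[:, 1], "level": levels}).to_csv(path, index=False)


def write_report(path, report: MetricReport) -> None:
    Path(path).write_text(report.to_json())
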