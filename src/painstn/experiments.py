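"""Scaled-down study protocols runnable on a desktop CPU.

The reference experiments ran on ~13k archive frames at 192x192; the
protocols here keep the study's structure — four-level labels with the
post-balancing class mix, subject-disjoint 10/5/10 splits, the four
ablation modes, dev-set model selection — at 48x48 resolution with a
narrow backbone, so a full ablation sweep finishes in minutes.  The
methods note documents the scaling choices.
"""

from __future__ import annotations

import numpy as np

from .model import PainLevelClassifier
from .published import LEVEL0_KEEP, LEVEL_COUNTS
from .synthetic import NuisanceConfig, generate_arrays

#: Class mix after balancing the no-pain class: (5260, 5260, 2456, 653).
BALANCED_COUNTS = (LEVEL0_KEEP,) + LEVEL_COUNTS[1:]
BALANCED_DISTRIBUTION = tuple(c / sum(BALANCED_COUNTS) for c in BALANCED_COUNTS)

#: Scaled experiment conditions (shared by tests and the acceptance run).
ABLATION_IMAGE_SIZE = 48
ABLATION_N_FRAMES = 600
#: dev/test pools are enlarged beyond the training pool (same subjects,
#: same generator stream) to cut snapshot-selection and evaluation noise
#: without changing the training cost
ABLATION_EVAL_MULTIPLIER = 2
ABLATION_BACKBONE = (8, 16, 16, 32)
ABLATION_LOC_FILTERS = 8
ABLATION_EPOCHS = 30
ABLATION_LR = 1e-2
ABLATION_LOC_LR_SCALE = 0.5
ABLATION_LOC_HEAD_DAMP = 0.05
ABLATION_STN_ANCHOR = 0.03
ABLATION_BATCH = 32

MODES = {
    "no-stn-no-att": dict(use_stn=False, use_attention=False),
    "stn-no-att": dict(use_stn=True, use_attention=False),
    "no-stn-att": dict(use_stn=False, use_attention=True),
    "stn-att": dict(use_stn=True, use_attention=True),
}


def _subject_splits(ds, train_pool: int | None = None):
    """10/5/10 subject-disjoint index sets (subjects assigned round-robin).

    ``train_pool`` caps the frame indices eligible for training, so a
    dataset generated with extra frames enlarges only the dev/test pools.
    """
    subs = sorted(set(ds.subjects))
    train_s, dev_s, test_s = set(subs[:10]), set(subs[10:15]), set(subs[15:])
    cap = len(ds.subjects) if train_pool is None else train_pool
    idx = {"train": [], "dev": [], "test": []}
    for i, s in enumerate(ds.subjects):
        if s in train_s:
            if i < cap:
                idx["train"].append(i)
        elif s in dev_s:
            idx["dev"].append(i)
        else:
            idx["test"].append(i)
    return {k: np.asarray(v) for k, v in idx.items()}


def _make_classifier(mode: str, seed: int, max_epochs: int = ABLATION_EPOCHS) -> PainLevelClassifier:
    return PainLevelClassifier(
        **MODES[mode],
        learning_rate=ABLATION_LR,
        momentum=0.9,
        batch_size=ABLATION_BATCH,
        max_epochs=max_epochs,
        image_size=ABLATION_IMAGE_SIZE,
        loc_filters=ABLATION_LOC_FILTERS,
        loc_lr_scale=ABLATION_LOC_LR_SCALE,
        loc_head_damp=ABLATION_LOC_HEAD_DAMP,
        stn_identity_anchor=ABLATION_STN_ANCHOR,
        backbone_filters=ABLATION_BACKBONE,
        dtype="float32",
        random_state=seed,
    )


def _ablation_dataset(seed: int, n_frames: int, nuisance: NuisanceConfig | None = None):
    return generate_arrays(
        n_frames,
        distribution=BALANCED_DISTRIBUTION,
        n_subjects=25,
        nuisance=nuisance,
        image_size=ABLATION_IMAGE_SIZE,
        seed=seed,
    )


def _fit_and_score(ds, splits, mode: str, seed: int) -> float:
    clf = _make_classifier(mode, seed)
    clf.fit(
        ds.images[splits["train"]],
        ds.levels[splits["train"]],
        X_dev=ds.images[splits["dev"]],
        y_dev=ds.levels[splits["dev"]],
    )
    report, _ = clf.evaluate(ds.images[splits["test"]], ds.levels[splits["test"]])
    return report.accuracy


def run_mode(mode: str, seed: int, n_frames: int = ABLATION_N_FRAMES, nuisance: NuisanceConfig | None = None) -> float:
    """Train one ablation mode on one seed; return test accuracy (percent)."""
    ds = _ablation_dataset(seed, n_frames, nuisance)
    return _fit_and_score(ds, _subject_splits(ds), mode, seed)


def ablation_experiment(
    seeds=(0, 1, 2, 3, 4),
    modes=tuple(MODES),
    n_frames: int = ABLATION_N_FRAMES,
    verbose: bool = False,
) -> dict[str, list[float]]:
    """Test accuracy of each ablation mode over several seeds.

    One synthetic dataset (full affine nuisance and clutter) is drawn per
    seed and shared by all modes, so the comparison is paired; dev/test
    pools are generated ABLATION_EVAL_MULTIPLIER times larger than the
    training pool for lower-variance model selection and evaluation.
    """
    results: dict[str, list[float]] = {m: [] for m in modes}
    for seed in seeds:
        ds = _ablation_dataset(seed, n_frames * ABLATION_EVAL_MULTIPLIER)
        splits = _subject_splits(ds, train_pool=n_frames)
        for mode in modes:
            acc = _fit_and_score(ds, splits, mode, seed)
            results[mode].append(acc)
            if verbose:
                print(f"seed={seed} mode={mode}: test accuracy {acc:.1f}%", flush=True)
    return results


def two_level_toy(seed: int = 0, n_frames: int = 500, max_epochs: int = 20) -> float:
    """Learnability floor: none-vs-excruciating at 48x48, low nuisance.

    Trains the baseline backbone (no STN, no attention) on 500 frames of
    levels {0, 3} with mild affine nuisance; returns test accuracy.
    """
    ds = generate_arrays(
        n_frames,
        distribution=(0.5, 0.0, 0.0, 0.5),
        n_subjects=25,
        nuisance=NuisanceConfig().scaled(0.25),
        image_size=ABLATION_IMAGE_SIZE,
        seed=seed,
    )
    splits = _subject_splits(ds)
    clf = _make_classifier("no-stn-no-att", seed, max_epochs=max_epochs)
    clf.fit(
        ds.images[splits["train"]],
        ds.levels[splits["train"]],
        X_dev=ds.images[splits["dev"]],
        y_dev=ds.levels[splits["dev"]],
    )
    report, _ = clf.evaluate(ds.images[splits["test"]], ds.levels[splits["test"]])
    return report.accuracy
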