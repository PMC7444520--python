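"""PSPI scoring, pain-level binning, dataset balancing and subject splits.

The Prkachin–Solomon Pain Intensity (PSPI) score summarizes the six
pain-relevant FACS action units of a frame:

    PSPI = AU4 + max(AU6, AU7) + max(AU9, AU10) + AU43

where AU4 (brow lowering), AU6/AU7 (orbital tightening) and AU9/AU10
(levator contraction) carry ordinal intensities 0-5 and AU43 (eye
closure) is binary, so PSPI ranges over 0-16.  Scores are binned into
four pain levels: 0 -> none, 1-2 -> weak, 3-5 -> intense, >= 6 ->
excruciating.  Because level 0 dominates real recordings, a fixed number
of level-0 frames is subsampled before the subject-disjoint
train/dev/test split.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import IntEnum
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

IMAGE_SIZE = 192

_AU_FIELDS = ("au4", "au6", "au7", "au9", "au10", "au43")


@dataclass(frozen=True)
class AUCoding:
    """Intensities of the six PSPI action units for one frame.

    au4, au6, au7, au9, au10 are ordinal 0-5 (FACS A-E mapped to 1-5,
    absence 0); au43 is the binary eye-closure indicator.
    """

    au4: int
    au6: int
    au7: int
    au9: int
    au10: int
    au43: int

    def __post_init__(self):
        for name in ("au4", "au6", "au7", "au9", "au10"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and 0 <= v <= 5):
                raise ValueError(f"{name} must be an integer in 0-5, got {v!r}")
        if self.au43 not in (0, 1):
            raise ValueError(f"au43 must be 0 or 1, got {self.au43!r}")


class PainLevel(IntEnum):
    """Four-level pain intensity derived from PSPI."""

    NONE = 0
    WEAK = 1
    INTENSE = 2
    EXCRUCIATING = 3

    @property
    def description(self) -> str:
        return {0: "None", 1: "Weak", 2: "Intense", 3: "Excruciating"}[int(self)]


@dataclass(frozen=True)
class LabeledFrame:
    """One frame: image reference, subject, PSPI score and its pain level."""

    image_path: str
    subject_id: str
    pspi: int
    level: PainLevel

    def __post_init__(self):
        if self.pspi < 0:
            raise ValueError("pspi must be non-negative")
        if self.level != bin_pspi(self.pspi):
            raise ValueError(
                f"level {int(self.level)} inconsistent with pspi {self.pspi} "
                f"(expected {int(bin_pspi(self.pspi))})"
            )


@dataclass(frozen=True)
class SplitSpec:
    """Disjoint subject assignment for train/dev/test."""

    train_subjects: frozenset
    dev_subjects: frozenset
    test_subjects: frozenset
    seed: int = 0

    def __post_init__(self):
        sets = (self.train_subjects, self.dev_subjects, self.test_subjects)
        total = sum(len(s) for s in sets)
        union = set().union(*sets)
        if len(union) != total:
            raise ValueError("split subject sets must be pairwise disjoint")

    @property
    def all_subjects(self) -> set:
        return set(self.train_subjects) | set(self.dev_subjects) | set(self.test_subjects)


def compute_pspi(au: AUCoding) -> int:
    """PSPI score of one AU coding (0-16)."""
    return au.au4 + max(au.au6, au.au7) + max(au.au9, au.au10) + au.au43


def bin_pspi(pspi: int) -> PainLevel:
    """Map a PSPI score to its pain level (0/1-2/3-5/>=6)."""
    if pspi < 0:
        raise ValueError(f"pspi must be non-negative, got {pspi}")
    if pspi == 0:
        return PainLevel.NONE
    if pspi <= 2:
        return PainLevel.WEAK
    if pspi <= 5:
        return PainLevel.INTENSE
    return PainLevel.EXCRUCIATING


def balance_level0(frames: list[LabeledFrame], n_keep: int, seed: int) -> list[LabeledFrame]:
    """Subsample the no-pain class to ``n_keep`` frames.

    Level-0 survivors are chosen by seeded uniform sampling without
    replacement; all other levels are kept untouched.  Original frame
    order is preserved, so the result is deterministic given the seed.
    """
    level0_idx = [i for i, f in enumerate(frames) if f.level == PainLevel.NONE]
    if n_keep > len(level0_idx):
        raise ValueError(
            f"cannot keep {n_keep} level-0 frames: only {len(level0_idx)} available"
        )
    rng = np.random.default_rng(seed)
    survivors = set(rng.choice(level0_idx, size=n_keep, replace=False).tolist())
    return [
        f
        for i, f in enumerate(frames)
        if f.level != PainLevel.NONE or i in survivors
    ]


def make_split_spec(subject_ids, sizes: tuple[int, int, int] = (10, 5, 10), seed: int = 0) -> SplitSpec:
    """Randomly partition subjects into train/dev/test of the given sizes."""
    subjects = sorted(set(subject_ids))
    if sum(sizes) != len(subjects):
        raise ValueError(f"split sizes {sizes} must sum to the {len(subjects)} subjects")
    rng = np.random.default_rng(seed)
    order = [subjects[i] for i in rng.permutation(len(subjects))]
    a, b = sizes[0], sizes[0] + sizes[1]
    return SplitSpec(
        train_subjects=frozenset(order[:a]),
        dev_subjects=frozenset(order[a:b]),
        test_subjects=frozenset(order[b:]),
        seed=seed,
    )


def split_by_subject(
    frames: list[LabeledFrame], spec: SplitSpec
) -> tuple[list[LabeledFrame], list[LabeledFrame], list[LabeledFrame]]:
    """Assign each frame to exactly one split by its subject id."""
    train, dev, test = [], [], []
    for f in frames:
        if f.subject_id in spec.train_subjects:
            train.append(f)
        elif f.subject_id in spec.dev_subjects:
            dev.append(f)
        elif f.subject_id in spec.test_subjects:
            test.append(f)
        else:
            raise ValueError(f"subject {f.subject_id!r} not present in the split spec")
    return train, dev, test


def load_and_normalize(path, image_size: int = IMAGE_SIZE) -> np.ndarray:
    """Load an 8-bit RGB image as a (size, size, 3) float array in [0, 1].

    Pixel bytes are scaled by 1/255 and the image is resampled bilinearly
    to the target size (the two linear operations commute, so resampling
    is done on the byte image).
    """
    img = Image.open(path)
    if img.mode != "RGB":
        raise ValueError(f"{path}: expected an RGB image, got mode {img.mode!r}")
    img = img.resize((image_size, image_size), Image.BILINEAR)
    return np.asarray(img, dtype=np.float64) / 255.0


def load_labels_csv(path) -> list[LabeledFrame]:
    """Read a labels CSV into validated frames.

    Required columns: ``frame_path``, ``subject_id`` and either the six
    AU columns (au4, au6, au7, au9, au10, au43) or a precomputed ``pspi``
    column.  When AU columns are present the PSPI is recomputed from them.
    """
    df = pd.read_csv(path)
    for col in ("frame_path", "subject_id"):
        if col not in df.columns:
            raise ValueError(f"labels CSV missing required column {col!r}")
    has_aus = all(c in df.columns for c in _AU_FIELDS)
    if not has_aus and "pspi" not in df.columns:
        raise ValueError("labels CSV needs either the six AU columns or a pspi column")
    frames = []
    for row in df.itertuples(index=False):
        if has_aus:
            au = AUCoding(*(int(getattr(row, c)) for c in _AU_FIELDS))
            pspi = compute_pspi(au)
        else:
            pspi = int(row.pspi)
        frames.append(
            LabeledFrame(
                image_path=str(row.frame_path),
                subject_id=str(row.subject_id),
                pspi=pspi,
                level=bin_pspi(pspi),
            )
        )
    return frames


def write_split_manifest(path, spec: SplitSpec) -> None:
    """Persist a split as JSON (subject ids per split plus the seed)."""
    payload = {
        "seed": spec.seed,
        "train_subjects": sorted(spec.train_subjects),
        "dev_subjects": sorted(spec.dev_subjects),
        "test_subjects": sorted(spec.test_subjects),
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_split_manifest(path) -> SplitSpec:
    payload = json.loads(Path(path).read_text())
    return SplitSpec(
        train_subjects=frozenset(payload["train_subjects"]),
        dev_subjects=frozenset(payload["dev_subjects"]),
        test_subjects=frozenset(payload["test_subjects"]),
        seed=int(payload.get("seed", 0)),
    )
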