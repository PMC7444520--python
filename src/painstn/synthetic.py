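"""Seeded generator of schematic face images with AU-driven deformations,
affine nuisance and background clutter.

The real shoulder-pain archive is access-restricted, so this module
draws face-like images from geometric primitives that carry the same
statistical structure the estimation pipeline assumes:

* a canonical face (oval, brows, eyes, pupils, nose, mouth) whose
  geometry deforms monotonically with the pain action units — AU4
  lowers and tilts the brows, AU6/AU7 narrow the eye apertures, AU43
  closes the eyes, AU9/AU10 raise and open the mouth/nose region;
* a loose-crop framing (``face_scale``): the face occupies only part of
  the frame, surrounded by background — the condition under which a
  spatial transformer can usefully crop/zoom onto the face;
* a random 2-D affine nuisance (rotation, translation, scale, skew)
  applied with the package's own grid/sampler, producing the black
  out-of-bounds edges a spatial transformer is meant to undo;
* seeded background clutter (random colored rectangles and ellipses,
  skin-like tones included) that attention gating is meant to suppress;
* per-subject jitter of face proportions so subject-disjoint splits are
  non-trivial.

Every frame's label is ``bin_pspi(compute_pspi(au))`` of its stored AU
record, and everything is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .labeling import AUCoding, LabeledFrame, PainLevel, bin_pspi, compute_pspi
from .published import LEVEL_PORTIONS
from .stn import affine_grid, bilinear_sample

#: Default level proportions: the archive's printed portions, normalized.
DEFAULT_DISTRIBUTION = tuple(p / sum(LEVEL_PORTIONS) for p in LEVEL_PORTIONS)


@dataclass(frozen=True)
class NuisanceConfig:
    """Ranges of the random affine nuisance applied to each frame.

    ``max_translation`` is a fraction of the image size; ``scale_jitter``
    s draws the scale factor from [1-s, 1+s]; ``max_skew`` bounds the
    shear coefficient.
    """

    max_rotation_deg: float = 35.0
    max_translation: float = 0.25
    scale_jitter: float = 0.20
    max_skew: float = 0.15

    def __post_init__(self):
        for name, v in asdict(self).items():
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")

    @classmethod
    def none(cls) -> "NuisanceConfig":
        return cls(0.0, 0.0, 0.0, 0.0)

    def scaled(self, factor: float) -> "NuisanceConfig":
        return NuisanceConfig(
            self.max_rotation_deg * factor,
            self.max_translation * factor,
            self.scale_jitter * factor,
            self.max_skew * factor,
        )


@dataclass(frozen=True)
class FaceSpec:
    """Full recipe for one synthetic frame."""

    au: AUCoding
    nuisance: NuisanceConfig = field(default_factory=NuisanceConfig)
    clutter_density: float = 0.35
    face_scale: float = 0.7
    image_size: int = 192
    seed: int = 0
    subject_jitter: dict | None = None

    def __post_init__(self):
        if not (0.0 <= self.clutter_density <= 1.0):
            raise ValueError("clutter_density must lie in [0, 1]")
        if not (0.2 <= self.face_scale <= 1.0):
            raise ValueError("face_scale must lie in [0.2, 1]")
        if self.image_size < 8:
            raise ValueError("image_size too small to draw a face")


@dataclass
class SyntheticDataset:
    """In-memory synthetic dataset plus its provenance."""

    images: np.ndarray  # (n, S, S, 3) in [0, 1]
    levels: np.ndarray  # (n,) ints 0-3
    subjects: list[str]
    aus: list[AUCoding]
    frames: list[LabeledFrame]
    level_distribution: tuple[float, ...]
    n_subjects: int
    seed: int


def _subject_jitter(seed: int, subject_idx: int) -> dict:
    rng = np.random.default_rng([seed, 1_000_003, subject_idx])
    return {
        "face_rx": 1.0 + rng.uniform(-0.08, 0.08),
        "face_ry": 1.0 + rng.uniform(-0.08, 0.08),
        "eye_dx": 1.0 + rng.uniform(-0.10, 0.10),
        "eye_y": rng.uniform(-0.02, 0.02),
        "mouth_y": rng.uniform(-0.02, 0.02),
        "tone": 1.0 + rng.uniform(-0.12, 0.12),
    }


def _ellipse(xx, yy, cx, cy, rx, ry):
    return ((xx - cx) / max(rx, 1e-6)) ** 2 + ((yy - cy) / max(ry, 1e-6)) ** 2 <= 1.0


def _bar(xx, yy, cx, cy, length, thick, angle):
    dx, dy = xx - cx, yy - cy
    c, s = np.cos(angle), np.sin(angle)
    u = dx * c + dy * s
    v = -dx * s + dy * c
    return (np.abs(u) <= length / 2) & (np.abs(v) <= thick / 2)


def render_canonical(spec: FaceSpec) -> np.ndarray:
    """Draw the cluttered, AU-deformed face before any affine nuisance."""
    s = spec.image_size
    au = spec.au
    j = spec.subject_jitter or {
        "face_rx": 1.0, "face_ry": 1.0, "eye_dx": 1.0, "eye_y": 0.0, "mouth_y": 0.0, "tone": 1.0,
    }
    rng = np.random.default_rng([spec.seed, 7])
    coords = (np.arange(s) + 0.5) / s
    bx, by = np.meshgrid(coords, coords)  # background coordinates
    # the face is drawn in a frame shrunk about the face center, emulating
    # a loose crop where the face occupies only part of the image and the
    # rest is background the transformer can learn to crop away
    xx = (bx - 0.5) / spec.face_scale + 0.5
    yy = (by - 0.52) / spec.face_scale + 0.52
    img = np.full((s, s, 3), 0.22)

    # background clutter: random colored rectangles and ellipses; colors
    # span the full RGB cube (including skin-like tones) so clutter is not
    # trivially separable from the face by color alone
    n_clutter = int(round(spec.clutter_density * 22))
    for _ in range(n_clutter):
        cx, cy = rng.uniform(0, 1, size=2)
        rx, ry = rng.uniform(0.03, 0.12, size=2)
        color = rng.uniform(0.0, 1.0, size=3)
        if rng.uniform() < 0.5:
            mask = _ellipse(bx, by, cx, cy, rx, ry)
        else:
            mask = (np.abs(bx - cx) <= rx) & (np.abs(by - cy) <= ry)
        img[mask] = color

    m67 = max(au.au6, au.au7)
    m910 = max(au.au9, au.au10)

    # face oval
    face_rx, face_ry = 0.30 * j["face_rx"], 0.38 * j["face_ry"]
    skin = np.array([0.82, 0.68, 0.58]) * j["tone"]
    img[_ellipse(xx, yy, 0.5, 0.52, face_rx, face_ry)] = np.clip(skin, 0, 1)

    eye_y = 0.43 + j["eye_y"]
    eye_dx = 0.13 * j["eye_dx"]
    brow_color = np.array([0.20, 0.12, 0.08])

    for side in (-1, 1):
        ex = 0.5 + side * eye_dx
        # brow: lowered and tilted inward-down by AU4, slightly thicker
        brow_y = eye_y - 0.095 + 0.020 * au.au4
        tilt = side * np.deg2rad(4.0 * au.au4)
        img[_bar(xx, yy, ex, brow_y, 0.12, 0.022 + 0.004 * au.au4, tilt)] = brow_color
        # eye aperture: narrowed by orbital tightening, closed by AU43
        aperture = 0.050 * (1.0 - 0.13 * m67)
        if au.au43:
            img[_bar(xx, yy, ex, eye_y, 0.13, 0.016, 0.0)] = brow_color  # closed lid line
        else:
            img[_ellipse(xx, yy, ex, eye_y, 0.080, aperture)] = np.array([0.97, 0.97, 0.95])
            img[_ellipse(xx, yy, ex, eye_y, 0.020, min(0.020, aperture))] = np.array([0.10, 0.08, 0.08])

    # nose: levator contraction wrinkles the bridge (darker, wider wedge)
    nose_w = 0.030 + 0.006 * m910
    img[_bar(xx, yy, 0.5, 0.55, nose_w * 2, 0.10, np.pi / 2)] = np.clip(skin * (0.82 - 0.04 * m910), 0, 1)

    # mouth: raised and opened with AU9/AU10
    mouth_y = 0.72 + j["mouth_y"] - 0.014 * m910
    mouth_ry = 0.020 + 0.009 * m910
    img[_ellipse(xx, yy, 0.5, mouth_y, 0.115 * (1.0 - 0.03 * m910), mouth_ry)] = np.array([0.45, 0.15, 0.15])
    return np.clip(img, 0.0, 1.0)


def sample_nuisance_theta(nuisance: NuisanceConfig, rng: np.random.Generator) -> np.ndarray:
    """Random affine parameters (6,) within the nuisance ranges."""
    rot = np.deg2rad(rng.uniform(-nuisance.max_rotation_deg, nuisance.max_rotation_deg))
    scale = 1.0 + rng.uniform(-nuisance.scale_jitter, nuisance.scale_jitter)
    shear = rng.uniform(-nuisance.max_skew, nuisance.max_skew)
    # translations are a fraction of the image; normalized coords span 2
    tx = 2.0 * rng.uniform(-nuisance.max_translation, nuisance.max_translation)
    ty = 2.0 * rng.uniform(-nuisance.max_translation, nuisance.max_translation)
    c, s = np.cos(rot), np.sin(rot)
    lin = np.array([[c, -s], [s, c]]) @ np.array([[1.0, shear], [0.0, 1.0]]) * scale
    return np.array([lin[0, 0], lin[0, 1], tx, lin[1, 0], lin[1, 1], ty])


def render_face(spec: FaceSpec) -> tuple[np.ndarray, dict]:
    """Render one frame: canonical face, then seeded affine nuisance.

    Returns the (S, S, 3) image in [0, 1] and a record holding the AU
    coding, PSPI, level and the nuisance theta actually applied.
    """
    canonical = render_canonical(spec)
    rng = np.random.default_rng([spec.seed, 13])
    theta = sample_nuisance_theta(spec.nuisance, rng)
    x = canonical.transpose(2, 0, 1)[None]
    grid = affine_grid(theta, spec.image_size, spec.image_size)
    img = bilinear_sample(x, grid)[0].transpose(1, 2, 0)
    pspi = compute_pspi(spec.au)
    record = {
        "au": spec.au,
        "pspi": pspi,
        "level": bin_pspi(pspi),
        "theta": theta,
        "seed": spec.seed,
    }
    return img, record


def sample_au_for_level(level: int, rng: np.random.Generator) -> AUCoding:
    """Draw an AU coding whose PSPI falls in the requested level's bin."""
    lo, hi = {0: (0, 0), 1: (1, 2), 2: (3, 5), 3: (6, 16)}[int(level)]
    target = int(rng.integers(lo, hi + 1))
    caps = [5, 5, 5, 1]  # au4, max(au6,au7), max(au9,au10), au43
    alloc = [0, 0, 0, 0]
    for _ in range(target):
        open_idx = [i for i in range(4) if alloc[i] < caps[i]]
        alloc[int(rng.choice(open_idx))] += 1

    def split_pair(m):
        other = int(rng.integers(0, m + 1)) if m > 0 else 0
        return (m, other) if rng.uniform() < 0.5 else (other, m)

    au6, au7 = split_pair(alloc[1])
    au9, au10 = split_pair(alloc[2])
    return AUCoding(au4=alloc[0], au6=au6, au7=au7, au9=au9, au10=au10, au43=alloc[3])


def generate_arrays(
    n: int,
    distribution: tuple[float, ...] = DEFAULT_DISTRIBUTION,
    n_subjects: int = 25,
    nuisance: NuisanceConfig | None = None,
    clutter_density: float = 0.35,
    face_scale: float = 0.7,
    image_size: int = 192,
    seed: int = 0,
) -> SyntheticDataset:
    """Generate an in-memory labeled dataset of schematic faces.

    Levels are drawn i.i.d. from ``distribution``; subjects are assigned
    round-robin with per-subject geometry jitter.
    """
    distribution = tuple(float(p) for p in distribution)
    if len(distribution) != 4 or any(p < 0 for p in distribution):
        raise ValueError("distribution must be 4 non-negative proportions")
    if abs(sum(distribution) - 1.0) > 1e-6:
        raise ValueError(f"distribution must sum to 1, got {sum(distribution)}")
    if n < n_subjects:
        raise ValueError("need at least one frame per subject")
    nuisance = nuisance if nuisance is not None else NuisanceConfig()
    rng = np.random.default_rng(seed)
    levels = rng.choice(4, size=n, p=distribution)
    jitters = [_subject_jitter(seed, i) for i in range(n_subjects)]

    images = np.empty((n, image_size, image_size, 3))
    subjects, aus, frames = [], [], []
    for i in range(n):
        subj_idx = i % n_subjects
        subj = f"s{subj_idx + 1:02d}"
        au = sample_au_for_level(levels[i], np.random.default_rng([seed, 3, i]))
        spec = FaceSpec(
            au=au,
            nuisance=nuisance,
            clutter_density=clutter_density,
            face_scale=face_scale,
            image_size=image_size,
            seed=int(np.random.default_rng([seed, 5, i]).integers(2**31)),
            subject_jitter=jitters[subj_idx],
        )
        img, rec = render_face(spec)
        images[i] = img
        subjects.append(subj)
        aus.append(au)
        frames.append(
            LabeledFrame(
                image_path=f"frame_{i:05d}.png",
                subject_id=subj,
                pspi=rec["pspi"],
                level=rec["level"],
            )
        )
        levels[i] = int(rec["level"])
    return SyntheticDataset(
        images=images,
        levels=np.asarray(levels, dtype=int),
        subjects=subjects,
        aus=aus,
        frames=frames,
        level_distribution=distribution,
        n_subjects=n_subjects,
        seed=seed,
    )


def generate_dataset(
    out_dir,
    n: int,
    distribution: tuple[float, ...] = DEFAULT_DISTRIBUTION,
    n_subjects: int = 25,
    nuisance: NuisanceConfig | None = None,
    clutter_density: float = 0.35,
    face_scale: float = 0.7,
    image_size: int = 192,
    seed: int = 0,
) -> SyntheticDataset:
    """Generate and write a dataset: PNG frames, labels CSV, manifest JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ds = generate_arrays(n, distribution, n_subjects, nuisance, clutter_density, face_scale, image_size, seed)
    rows = []
    for i, (frame, au) in enumerate(zip(ds.frames, ds.aus)):
        png = out_dir / frame.image_path
        Image.fromarray((ds.images[i] * 255.0 + 0.5).astype(np.uint8)).save(png)
        rows.append(
            {
                "frame_path": frame.image_path,
                "subject_id": frame.subject_id,
                "au4": au.au4, "au6": au.au6, "au7": au.au7,
                "au9": au.au9, "au10": au.au10, "au43": au.au43,
            }
        )
    pd.DataFrame(rows).to_csv(out_dir / "labels.csv", index=False)
    manifest = {
        "n": n,
        "distribution": list(distribution),
        "n_subjects": n_subjects,
        "nuisance": asdict(nuisance if nuisance is not None else NuisanceConfig()),
        "clutter_density": clutter_density,
        "face_scale": face_scale,
        "image_size": image_size,
        "seed": seed,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return ds
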