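"""PSPI scoring, pain-level binning, balancing and subject splits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from PIL import Image

from painstn.labeling import (
    AUCoding,
    LabeledFrame,
    PainLevel,
    SplitSpec,
    balance_level0,
    bin_pspi,
    compute_pspi,
    load_and_normalize,
    load_labels_csv,
    make_split_spec,
    read_split_manifest,
    split_by_subject,
    write_split_manifest,
)
from painstn.published import LEVEL_COUNTS, LEVEL_PORTIONS

au_intensity = st.integers(min_value=0, max_value=5)
au_strategy = st.builds(
    AUCoding,
    au4=au_intensity, au6=au_intensity, au7=au_intensity,
    au9=au_intensity, au10=au_intensity,
    au43=st.integers(min_value=0, max_value=1),
)


@pytest.mark.parametrize(
    "au, expected",
    [
        (AUCoding(0, 0, 0, 0, 0, 0), 0),
        (AUCoding(5, 5, 5, 5, 5, 1), 16),
        (AUCoding(1, 2, 1, 0, 3, 0), 6),
    ],
)
def test_pspi_formula(au, expected):
    assert compute_pspi(au) == expected


@pytest.mark.parametrize("bad", [dict(au4=6), dict(au6=-1), dict(au43=2), dict(au10=7)])
def test_au_validation_names_offending_unit(bad):
    fields = dict(au4=0, au6=0, au7=0, au9=0, au10=0, au43=0)
    fields.update(bad)
    (unit,) = bad
    with pytest.raises(ValueError, match=unit):
        AUCoding(**fields)


@given(au=au_strategy, bump=st.sampled_from(["au4", "au6", "au7", "au9", "au10", "au43"]))
@settings(max_examples=200, deadline=None)
def test_pspi_monotone_in_every_unit(au, bump):
    """Raising any single AU intensity can never lower the PSPI score."""
    cap = 1 if bump == "au43" else 5
    current = getattr(au, bump)
    if current >= cap:
        return
    raised = AUCoding(**{**au.__dict__, bump: current + 1})
    assert compute_pspi(raised) >= compute_pspi(au)


@pytest.mark.parametrize(
    "pspi, level", [(0, 0), (1, 1), (2, 1), (3, 2), (4, 2), (5, 2), (6, 3), (16, 3), (40, 3)]
)
def test_bin_pspi(pspi, level):
    assert bin_pspi(pspi) == PainLevel(level)


def test_bin_pspi_rejects_negative():
    with pytest.raises(ValueError):
        bin_pspi(-1)


@given(au=au_strategy)
@settings(max_examples=200, deadline=None)
def test_binned_pspi_covers_only_four_levels(au):
    assert bin_pspi(compute_pspi(au)) in set(PainLevel)


def test_level_descriptions():
    assert [PainLevel(i).description for i in range(4)] == ["None", "Weak", "Intense", "Excruciating"]


def test_published_level_portions_recompute():
    """Portions recomputed from the published per-level counts match the
    printed one-decimal percentages (82.7 / 10.9 / 5.1 / 1.3)."""
    total = sum(LEVEL_COUNTS)
    recomputed = [round(100.0 * c / total, 1) for c in LEVEL_COUNTS]
    assert recomputed == list(LEVEL_PORTIONS)


def _frames(level_counts, n_subjects=25):
    frames = []
    pspi_for_level = {0: 0, 1: 1, 2: 3, 3: 6}
    i = 0
    for level, count in enumerate(level_counts):
        for _ in range(count):
            frames.append(
                LabeledFrame(
                    image_path=f"f{i}.png",
                    subject_id=f"s{i % n_subjects:02d}",
                    pspi=pspi_for_level[level],
                    level=PainLevel(level),
                )
            )
            i += 1
    return frames


class TestBalanceLevel0:
    def test_published_counts_balance(self):
        """The archive's counts (40007, 5260, 2456, 653) with n_keep=5260
        leave level counts (5260, 5260, 2456, 653)."""
        frames = _frames(LEVEL_COUNTS)
        kept = balance_level0(frames, n_keep=5260, seed=0)
        counts = np.bincount([int(f.level) for f in kept], minlength=4)
        assert counts.tolist() == [5260, 5260, 2456, 653]

    def test_noop_when_keeping_all(self):
        frames = _frames((30, 10, 5, 2))
        assert balance_level0(frames, n_keep=30, seed=3) == frames

    def test_deterministic_given_seed(self):
        frames = _frames((200, 40, 20, 8))
        a = balance_level0(frames, n_keep=50, seed=11)
        b = balance_level0(frames, n_keep=50, seed=11)
        assert a == b
        c = balance_level0(frames, n_keep=50, seed=12)
        assert a != c

    def test_overdraw_raises(self):
        with pytest.raises(ValueError):
            balance_level0(_frames((5, 1, 1, 1)), n_keep=6, seed=0)


class TestSubjectSplit:
    def test_every_subject_in_exactly_one_split(self):
        subjects = [f"s{i:02d}" for i in range(25)]
        spec = make_split_spec(subjects, sizes=(10, 5, 10), seed=4)
        assert len(spec.train_subjects) == 10
        assert len(spec.dev_subjects) == 5
        assert len(spec.test_subjects) == 10
        assert spec.all_subjects == set(subjects)

    def test_frames_follow_their_subject(self):
        frames = _frames((100, 30, 20, 10))
        spec = make_split_spec({f.subject_id for f in frames}, sizes=(10, 5, 10), seed=1)
        tr, dv, te = split_by_subject(frames, spec)
        assert len(tr) + len(dv) + len(te) == len(frames)
        assert {f.subject_id for f in tr} <= set(spec.train_subjects)
        assert {f.subject_id for f in dv} <= set(spec.dev_subjects)
        assert {f.subject_id for f in te} <= set(spec.test_subjects)

    def test_order_invariance(self, rng):
        frames = _frames((60, 20, 10, 6))
        spec = make_split_spec({f.subject_id for f in frames}, sizes=(10, 5, 10), seed=2)
        shuffled = [frames[i] for i in rng.permutation(len(frames))]
        for a, b in zip(split_by_subject(frames, spec), split_by_subject(shuffled, spec)):
            assert set(a) == set(b)

    def test_single_subject_dataset(self):
        frames = [LabeledFrame("a.png", "solo", 0, PainLevel.NONE)]
        spec = SplitSpec(frozenset({"solo"}), frozenset({"x"}), frozenset({"y"}))
        tr, dv, te = split_by_subject(frames, spec)
        assert tr == frames and dv == [] and te == []

    def test_unknown_subject_raises(self):
        frames = [LabeledFrame("a.png", "ghost", 0, PainLevel.NONE)]
        spec = SplitSpec(frozenset({"a"}), frozenset({"b"}), frozenset({"c"}))
        with pytest.raises(ValueError, match="ghost"):
            split_by_subject(frames, spec)

    def test_overlapping_spec_rejected(self):
        with pytest.raises(ValueError):
            SplitSpec(frozenset({"a"}), frozenset({"a"}), frozenset({"c"}))

    def test_manifest_round_trip(self, tmp_path):
        spec = make_split_spec([f"s{i}" for i in range(25)], seed=9)
        write_split_manifest(tmp_path / "split.json", spec)
        assert read_split_manifest(tmp_path / "split.json") == spec


class TestLoadAndNormalize:
    @pytest.mark.parametrize("byte, value", [(255, 1.0), (0, 0.0)])
    def test_constant_images(self, tmp_path, byte, value):
        p = tmp_path / "c.png"
        Image.fromarray(np.full((64, 48, 3), byte, dtype=np.uint8)).save(p)
        out = load_and_normalize(p)
        assert out.shape == (192, 192, 3)
        assert np.allclose(out, value)

    def test_random_image_bounds_and_shape(self, tmp_path, rng):
        p = tmp_path / "r.png"
        Image.fromarray(rng.integers(0, 256, size=(30, 50, 3), dtype=np.uint8), "RGB").save(p)
        out = load_and_normalize(p)
        assert out.shape == (192, 192, 3)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_non_rgb_rejected(self, tmp_path):
        p = tmp_path / "g.png"
        Image.fromarray(np.zeros((10, 10), dtype=np.uint8), "L").save(p)
        with pytest.raises(ValueError, match="RGB"):
            load_and_normalize(p)

    def test_unreadable_file(self, tmp_path):
        with pytest.raises(OSError):
            load_and_normalize(tmp_path / "missing.png")


def test_labels_csv_with_au_columns(tmp_path):
    csv = tmp_path / "labels.csv"
    csv.write_text(
        "frame_path,subject_id,au4,au6,au7,au9,au10,au43\n"
        "a.png,s01,0,0,0,0,0,0\n"
        "b.png,s02,5,5,5,5,5,1\n"
    )
    frames = load_labels_csv(csv)
    assert frames[0].pspi == 0 and frames[0].level == PainLevel.NONE
    assert frames[1].pspi == 16 and frames[1].level == PainLevel.EXCRUCIATING


def test_labels_csv_with_pspi_column(tmp_path):
    csv = tmp_path / "labels.csv"
    csv.write_text("frame_path,subject_id,pspi\na.png,s01,4\n")
    assert load_labels_csv(csv)[0].level == PainLevel.INTENSE


def test_labels_csv_missing_columns(tmp_path):
    csv = tmp_path / "labels.csv"
    csv.write_text("frame_path,subject_id\na.png,s01\n")
    with pytest.raises(ValueError):
        load_labels_csv(csv)
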