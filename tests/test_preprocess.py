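"""Preprocessing contracts: overlay stripping, ROI extraction vs brute-force
oracle, zero-padding conservation, filename grammar, quality filtering."""

import datetime

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from sonosex import synthdata as sd
from sonosex.naming import FilenameError, FrameMeta, format_filename, parse_filename
from sonosex.preprocess import (
    BoundingBox,
    EmptySpecimenError,
    QualityRuleSet,
    extract_roi,
    filter_quality,
    strip_overlay,
    zero_pad,
)


def brute_force_roi(img: np.ndarray, threshold: int = 5) -> BoundingBox:
    """Independent oracle: label components (8-connectivity), rank by
    hole-filled area, take the bounding box of above-threshold coordinates."""
    mask = img > threshold
    labels, n = ndimage.label(mask, structure=np.ones((3, 3)))
    best_key, best_box = None, None
    for lab in range(1, n + 1):
        comp = labels == lab
        area = int(ndimage.binary_fill_holes(comp).sum())
        rows, cols = np.nonzero(comp)
        box = (rows.min(), cols.min(), rows.max() - rows.min() + 1, cols.max() - cols.min() + 1)
        key = (-area, box[0], box[1])
        if best_key is None or key < best_key:
            best_key, best_box = key, box
    return BoundingBox(*best_box)


class TestStripOverlay:
    def test_known_border_removed_exactly(self, clean_spec):
        art = sd.ArtifactProfile(overlay_border=True, border_px=20, text_band_px=0)
        img = sd.render_frame(clean_spec, 0, art, seed=1)
        out = strip_overlay(img, "auto")
        assert out.shape == (img.shape[0] - 40, img.shape[1] - 40)

    def test_zero_margins_is_identity(self, clean_frame):
        assert np.array_equal(strip_overlay(clean_frame, (0, 0, 0, 0)), clean_frame)

    def test_auto_on_overlay_free_image_is_identity(self, clean_frame):
        assert np.array_equal(strip_overlay(clean_frame, "auto"), clean_frame)

    def test_text_band_also_removed(self, clean_spec):
        art = sd.ArtifactProfile(overlay_border=True, border_px=12, text_band_px=8)
        img = sd.render_frame(clean_spec, 0, art, seed=1)
        out = strip_overlay(img, "auto", text_band=8)
        assert out.shape == (img.shape[0] - 24 - 8, img.shape[1] - 24)
        # the pseudo-text band must be gone: no overlay-text pixels remain
        assert not (out == sd.OVERLAY_TEXT_VALUE).all(axis=1).any()

    def test_margins_consuming_image_rejected(self, clean_frame):
        with pytest.raises(ValueError):
            strip_overlay(clean_frame, (64, 64, 0, 0))


class TestExtractROI:
    def test_single_rectangle_box(self):
        img = np.zeros((100, 100), dtype=np.uint8)
        img[10:30, 40:80] = 200
        box, crop = extract_roi(img)
        assert (box.row0, box.col0, box.height, box.width) == (10, 40, 20, 40)
        assert crop.shape == (20, 40)
        assert (crop == 200).all()

    def test_largest_of_two_components_wins(self):
        img = np.zeros((100, 100), dtype=np.uint8)
        img[5:15, 5:25] = 100  # 200 px^2
        img[50:70, 40:70] = 100  # 600 px^2
        box, _ = extract_roi(img)
        assert (box.row0, box.col0, box.height, box.width) == (50, 40, 20, 30)

    def test_all_zero_image_raises_empty_specimen(self):
        with pytest.raises(EmptySpecimenError):
            extract_roi(np.zeros((32, 32), dtype=np.uint8))

    def test_threshold_is_strict(self):
        img = np.full((10, 10), 5, dtype=np.uint8)  # exactly at threshold: background
        with pytest.raises(EmptySpecimenError):
            extract_roi(img)
        img[3, 3] = 6
        box, _ = extract_roi(img)
        assert (box.height, box.width) == (1, 1)

    def test_idempotent(self, clean_frame):
        box1, crop1 = extract_roi(clean_frame)
        box2, crop2 = extract_roi(crop1)
        assert (box2.row0, box2.col0) == (0, 0)
        assert crop2.shape == crop1.shape

    def test_equals_brute_force_oracle_on_random_phantoms(self):
        cfg = sd.DatasetConfig(
            n_per_sex=10, frames_min=2, frames_max=3, canvas=(48, 48),
            ghost_rate=0.3, suppress_rate=0.1, truncate_rate=0.1,
            overlay_border_px=0, overlay_text_px=0,
        )
        frames, _ = sd.generate_frames(cfg, seed=13)
        for img in frames:
            box, _ = extract_roi(img)
            oracle = brute_force_roi(img)
            assert box == oracle


class TestZeroPad:
    def test_nonzero_support_within_window(self):
        img = np.full((20, 30), 7, dtype=np.uint8)
        out = zero_pad(img, 64, 64)
        rows, cols = np.nonzero(out)
        assert rows.max() - rows.min() + 1 <= 20
        assert cols.max() - cols.min() + 1 <= 30
        assert out.shape == (64, 64)

    def test_identity_when_target_equals_input(self, clean_frame):
        out = zero_pad(clean_frame, *clean_frame.shape)
        assert np.array_equal(out, clean_frame)

    def test_intensity_sum_conserved(self, clean_frame):
        out = zero_pad(clean_frame, 200, 180)
        assert int(out.sum()) == int(clean_frame.sum())

    def test_target_smaller_than_image_rejected(self, clean_frame):
        with pytest.raises(ValueError):
            zero_pad(clean_frame, 10, 10)


class TestFilenameGrammar:
    def test_example_parses(self):
        meta = parse_filename("A012_BML_F_large_20240301_03.png")
        assert meta == FrameMeta("A012", "BML", "F", "large", datetime.date(2024, 3, 1), 3)

    def test_bad_sex_names_field(self):
        with pytest.raises(FilenameError, match="sex"):
            parse_filename("A012_BML_X_large_20240301_03.png")

    @pytest.mark.parametrize(
        "name,field",
        [
            ("A012_BML_F_medium_20240301_03.png", "size_class"),
            ("A012_BML_F_large_2024030_03.png", "date"),
            ("A012_BML_F_large_20240301.png", "structure"),
        ],
    )
    def test_malformed_names_report_field(self, name, field):
        with pytest.raises(FilenameError, match=field):
            parse_filename(name)

    @settings(max_examples=200, deadline=None)
    @given(
        ind=st.from_regex(r"[A-Za-z0-9]{1,8}", fullmatch=True),
        loc=st.from_regex(r"[A-Za-z0-9]{1,6}", fullmatch=True),
        sex=st.sampled_from(["F", "M"]),
        size=st.sampled_from(["small", "large"]),
        date=st.dates(datetime.date(2000, 1, 1), datetime.date(2030, 12, 31)),
        frame=st.integers(0, 99),
    )
    def test_round_trip(self, ind, loc, sex, size, date, frame):
        meta = FrameMeta(ind, loc, sex, size, date, frame)
        assert parse_filename(format_filename(meta)) == meta


class TestQualityFilter:
    @staticmethod
    def _dataset_with_defects():
        cfg = sd.DatasetConfig(
            n_per_sex=5, frames_min=3, frames_max=3, canvas=(96, 96),
            ghost_rate=0, suppress_rate=0, truncate_rate=0,
            overlay_border_px=0, overlay_text_px=0,
        )
        frames, manifest = sd.generate_frames(cfg, seed=3)
        # re-render 10 frames with suppressed anatomy (ground truth known)
        bad_idx = list(range(0, 30, 3))
        for i in bad_idx:
            row = manifest.iloc[i]
            spec = sd.sample_individual(
                row["sex"], row["size_class"], seed=3,
                index=int(row["individual_id"][2:]),
                canvas=(96, 96),
            )
            frames[i] = sd.render_frame(
                spec, int(row["frame_index"]), sd.ArtifactProfile(suppress_gonad=True), seed=3
            )
            manifest.loc[manifest.index[i], ["quality_pass", "defect_codes"]] = [False, "b"]
        return frames, manifest, bad_idx

    def test_defect_free_dataset_keeps_everything(self):
        cfg = sd.DatasetConfig(
            n_per_sex=4, frames_min=3, frames_max=5, canvas=(96, 96),
            ghost_rate=0, suppress_rate=0, truncate_rate=0,
            overlay_border_px=0, overlay_text_px=0,
        )
        frames, manifest = sd.generate_frames(cfg, seed=7)
        kept, excluded = filter_quality(manifest, images=frames)
        assert len(excluded) == 0
        assert len(kept) == len(manifest)

    def test_suppressed_frames_and_only_those_excluded_under_b(self):
        frames, manifest, bad_idx = self._dataset_with_defects()
        kept, excluded = filter_quality(manifest, images=frames)
        assert sorted(excluded.index) == sorted(manifest.index[bad_idx])
        assert (excluded["qc_codes"].str.contains("b")).all()

    def test_all_rules_disabled_keeps_input(self):
        frames, manifest, _ = self._dataset_with_defects()
        rules = QualityRuleSet(check_ghost=False, check_anatomy=False, check_capture=False)
        kept, excluded = filter_quality(manifest, rules, images=frames)
        assert kept.equals(manifest)
        assert len(excluded) == 0

    def test_ghost_and_truncation_detected(self):
        cfg = sd.DatasetConfig(
            n_per_sex=3, frames_min=2, frames_max=2, canvas=(96, 96),
            ghost_rate=0, suppress_rate=0, truncate_rate=0,
            overlay_border_px=0, overlay_text_px=0,
        )
        frames, manifest = sd.generate_frames(cfg, seed=17)
        spec = sd.sample_individual("F", "large", seed=17, index=0, canvas=(96, 96))
        frames[0] = sd.render_frame(spec, 0, sd.ArtifactProfile(echo_ghost=True), seed=17)
        frames[1] = sd.render_frame(spec, 1, sd.ArtifactProfile(truncate_fov=True), seed=17)
        _, excluded = filter_quality(manifest, images=frames)
        codes = dict(zip(excluded["path"], excluded["qc_codes"]))
        assert "a" in codes[manifest["path"].iloc[0]]
        assert "c" in codes[manifest["path"].iloc[1]]

    def test_qc_never_reads_sex(self):
        """Label-leakage guard: flipping every sex label leaves QC unchanged."""
        frames, manifest, _ = self._dataset_with_defects()
        kept1, exc1 = filter_quality(manifest, images=frames)
        flipped = manifest.copy()
        flipped["sex"] = flipped["sex"].map({"F": "M", "M": "F"})
        kept2, exc2 = filter_quality(flipped, images=frames)
        assert list(kept1.index) == list(kept2.index)
        assert list(exc1.index) == list(exc2.index)
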