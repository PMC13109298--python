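"""Vegetation index formula, profile-based range/row detection, prompts."""

import numpy as np
import pytest

from canoplot.backends import ClassicalBackend
from canoplot.prompts import (
    RowLayout,
    build_layout,
    detect_ranges,
    detect_rows,
    make_prompts,
    segment_rows,
    vegetation_index,
)


def _veg_from_mask(mask):
    """Build a VegetationMap-compatible image: green where mask, soil else."""
    img = np.empty((3,) + mask.shape, dtype=np.uint8)
    for c, v in enumerate((118, 98, 76)):
        img[c] = v
    for c, v in enumerate((56, 112, 48)):
        img[c][mask] = v
    return vegetation_index(img)


class TestVegetationIndex:
    def test_pure_green_scores_three(self):
        img = np.zeros((3, 1, 1), np.uint8)
        img[1] = 255
        v = vegetation_index(img)
        assert v.score[0, 0] == pytest.approx(3.0)
        assert v.mask[0, 0]

    def test_gray_is_soil(self):
        img = np.full((3, 1, 1), 128, np.uint8)
        v = vegetation_index(img)
        assert v.score[0, 0] == pytest.approx(-0.13333, abs=1e-4)
        assert not v.mask[0, 0]

    def test_black_scores_zero_non_vegetation(self):
        v = vegetation_index(np.zeros((3, 2, 2), np.uint8))
        assert (v.score == 0).all() and not v.mask.any()

    def test_mask_iff_positive_score(self, rng):
        img = rng.integers(0, 256, size=(3, 20, 20), dtype=np.uint8)
        v = vegetation_index(img)
        np.testing.assert_array_equal(v.mask, v.score > 0)
        assert np.isfinite(v.score).all()


class TestDetectRanges:
    def test_two_columns_split_at_valley_midpoint(self):
        mask = np.zeros((50, 500), bool)
        mask[:, 100:200] = True
        mask[:, 300:400] = True
        intervals = detect_ranges(_veg_from_mask(mask))
        assert len(intervals) == 2
        # boundary at the midpoint of the 200..300 valley
        assert intervals[0][1] == pytest.approx(250, abs=2)
        assert intervals[1][0] == pytest.approx(250, abs=2)

    def test_full_width_vegetation_single_interval(self):
        mask = np.ones((20, 100), bool)
        assert detect_ranges(_veg_from_mask(mask)) == [(0, 100)]

    def test_empty_mask_no_intervals(self):
        mask = np.zeros((20, 100), bool)
        assert detect_ranges(_veg_from_mask(mask)) == []


class TestDetectRows:
    def test_two_bands_peak_positions(self):
        mask = np.zeros((200, 100), bool)
        mask[45:56, :] = True
        mask[136:147, :] = True
        veg = _veg_from_mask(mask)
        ys = detect_rows(veg, (0, 100), smooth_px=5, min_separation_px=20)
        assert len(ys) == 2
        assert ys[0] == pytest.approx(50, abs=2)
        assert ys[1] == pytest.approx(141, abs=2)

    def test_single_band(self):
        mask = np.zeros((100, 50), bool)
        mask[40:60, :] = True
        ys = detect_rows(_veg_from_mask(mask), (0, 50), smooth_px=3)
        assert len(ys) == 1

    def test_flat_subthreshold_profile_empty(self):
        mask = np.zeros((100, 50), bool)
        assert detect_rows(_veg_from_mask(mask), (0, 50)) == []


class TestLayoutOracle:
    def test_recovers_generator_grid_exactly(self, segmented_field):
        """Range/row detection equals the known planting grid (+/- 3 px)."""
        cfg, ortho, _, truth, veg, layout, _ = segmented_field
        assert len(layout.range_intervals) == cfg.n_ranges
        assert all(len(r) == 2 * cfg.n_beds for r in layout.row_ys)
        pitch_px = cfg.range_pitch_m * 100 / cfg.gsd_cm
        margin_px = cfg.margin_m * 100 / cfg.gsd_cm
        for ri, ys in enumerate(layout.row_ys):
            for bi in range(cfg.n_beds):
                bed_top = margin_px + bi * cfg.bed_width_m * 100 / cfg.gsd_cm
                half = cfg.row_spacing_m / 2 * 100 / cfg.gsd_cm
                bed_c = bed_top + cfg.bed_width_m / 2 * 100 / cfg.gsd_cm
                assert ys[2 * bi] == pytest.approx(bed_c - half, abs=3)
                assert ys[2 * bi + 1] == pytest.approx(bed_c + half, abs=3)


class TestMakePrompts:
    def _layout(self):
        cents = [(50.0, 20.0, 0, 0), (50.0, 60.0, 0, 1), (50.0, 100.0, 0, 2)]
        return RowLayout(range_intervals=[(0, 100)], row_ys=[[20.0, 60.0, 100.0]], centroids=cents)

    def test_neighbours_become_background(self):
        layout = self._layout()
        fg, bg = make_prompts(layout, layout.centroids[1])
        assert fg == [(50.0, 60.0)]
        assert (50.0, 20.0) in bg and (50.0, 100.0) in bg

    def test_single_centroid_no_background(self):
        layout = RowLayout([(0, 10)], [[5.0]], [(5.0, 5.0, 0, 0)])
        fg, bg = make_prompts(layout, layout.centroids[0])
        assert fg == [(5.0, 5.0)] and bg == []

    def test_one_prompt_set_per_centroid(self, segmented_field):
        *_, layout, _ = segmented_field
        prompt_sets = [make_prompts(layout, c) for c in layout.centroids]
        assert len(prompt_sets) == len(layout.centroids)


class TestSegmentRows:
    def test_labels_cover_truth_masks(self, segmented_field):
        cfg, ortho, _, truth, veg, layout, labels = segmented_field
        assert labels.max() == 2 * cfg.n_beds * cfg.n_ranges
        np.testing.assert_array_equal(labels > 0, truth.canopy_mask)

    def test_disjoint_plots_have_disjoint_labels(self, segmented_field):
        *_, truth, veg, layout, labels = segmented_field
        # each label maps into exactly one truth plot
        for lab in np.unique(labels)[1:]:
            truth_ids = np.unique(truth.label_raster[labels == lab])
            assert len(truth_ids) == 1 and truth_ids[0] != 0

    def test_no_label_outside_field_mask(self, segmented_field):
        *_, truth, veg, layout, labels = segmented_field
        assert not (labels[~veg.mask] > 0).any()

    def test_deterministic(self, segmented_field):
        cfg, ortho, *_ , layout, labels = segmented_field
        again = segment_rows(ClassicalBackend(), ortho.values, layout)
        np.testing.assert_array_equal(labels, again)
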