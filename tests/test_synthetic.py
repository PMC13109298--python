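"""Generator contracts: determinism, layout, trait statistics, rotation."""

import numpy as np
import pytest

from canoplot.metrics import iou
from canoplot.prompts import vegetation_index
from canoplot.synthetic import (
    FieldConfig,
    generate_field,
    rotate_field,
    sample_canopy_heights,
)


class TestGenerateField:
    def test_same_seed_bit_identical(self):
        cfg = FieldConfig(n_ranges=2, n_beds=2, gsd_cm=2.0, seed=9)
        o1, d1, t1 = generate_field(cfg)
        o2, d2, t2 = generate_field(cfg)
        np.testing.assert_array_equal(o1.values, o2.values)
        np.testing.assert_array_equal(d1.values, d2.values)
        np.testing.assert_array_equal(t1.label_raster, t2.label_raster)
        assert [p.ch_cm for p in t1.plots] == [p.ch_cm for p in t2.plots]

    def test_plot_count_without_dropping(self, small_field):
        _, _, _, truth = small_field
        assert len(truth.plots) == 3 * 4

    def test_heights_within_configured_range(self, small_field):
        cfg, _, _, truth = small_field
        lo, hi = cfg.ch_range_cm
        assert all(lo <= p.ch_cm <= hi for p in truth.plots)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            FieldConfig(n_ranges=0)
        with pytest.raises(ValueError):
            FieldConfig(ch_range_cm=(40.0, 16.0))
        with pytest.raises(ValueError):
            FieldConfig(missing_plot_rate=1.5)

    def test_canopy_pixels_are_vegetation_soil_is_not(self, small_field):
        """The rendered colors must drive the ExG-ExR threshold correctly."""
        _, ortho, _, truth = small_field
        veg = vegetation_index(ortho.values)
        canopy = truth.canopy_mask
        assert veg.mask[canopy].all()
        assert not veg.mask[~canopy].any()

    def test_dsm_minus_terrain_equals_canopy_plus_furrows(self, small_field):
        """With zero noise the DSM decomposes exactly into terrain + canopy."""
        _, _, dsm, truth = small_field
        H, W = dsm.shape
        ys, xs = np.mgrid[0:H, 0:W]
        residual = dsm.values - truth.terrain(xs, ys)
        assert np.abs(residual[~truth.canopy_mask]).max() < 1e-6
        heights = {p.plot_id: p.ch_cm for p in truth.plots}
        for pid in list(heights)[:5]:
            peak = residual[truth.label_raster == pid].max() * 100
            assert peak == pytest.approx(heights[pid], abs=0.15)

    def test_each_canopy_pixel_in_exactly_one_mask(self, small_field):
        _, _, _, truth = small_field
        labels = truth.label_raster
        present = set(np.unique(labels)) - {0}
        assert present == {p.plot_id for p in truth.plots}

    def test_missing_and_single_row_rates(self):
        cfg = FieldConfig(n_ranges=5, n_beds=8, gsd_cm=2.0, seed=4,
                          missing_plot_rate=0.2, single_row_rate=0.3)
        _, _, truth = generate_field(cfg)
        assert len(truth.plots) < 40
        assert any(p.single_row for p in truth.plots)


class TestHeightDistribution:
    def test_sample_mean_matches_reference_statistics(self):
        """Mean of 1000 plot heights lands within 24.8 +/- 0.6 cm.

        Cross-checked against an independent rejection-sampling oracle drawn
        from the same calibrated parent normal.
        """
        cfg = FieldConfig()
        rng = np.random.default_rng(77)
        heights = sample_canopy_heights(cfg, 1000, rng)
        assert abs(heights.mean() - 24.8) < 0.6
        assert abs(heights.std(ddof=1) - 6.37) < 0.7
        # oracle: rejection sampling from the parent law, independent of rvs
        from canoplot.synthetic import _truncnorm_parent_params

        mu, sigma = _truncnorm_parent_params(24.8, 6.37, 16.0, 40.0)
        rng_o = np.random.default_rng(78)
        draws = rng_o.normal(mu, sigma, size=200_000)
        draws = draws[(draws >= 16) & (draws <= 40)]
        assert abs(draws.mean() - 24.8) < 0.1
        assert abs(heights.mean() - draws.mean()) < 0.6


class TestRotateField:
    def test_angle_zero_is_identity(self, small_field):
        _, ortho, dsm, truth = small_field
        o2, d2, t2 = rotate_field(ortho, dsm, truth, 0.0)
        assert o2 is ortho and d2 is dsm and t2 is truth

    def test_rotate_90_transposes(self, small_field):
        _, ortho, dsm, truth = small_field
        o2, _, t2 = rotate_field(ortho, dsm, truth, 90.0)
        assert o2.shape == ortho.shape[::-1]
        m90 = t2.label_raster > 0
        # 90 deg rotation of the mask equals numpy's rot90 up to the
        # half-pixel center convention
        expected = np.rot90(truth.label_raster > 0, k=1)
        inter = (m90 & expected).sum()
        union = (m90 | expected).sum()
        assert inter / union > 0.97

    def test_truth_follows_raster(self, small_field):
        _, ortho, dsm, truth = small_field
        _, _, t2 = rotate_field(ortho, dsm, truth, 30.0)
        lab = t2.label_raster
        for p in t2.plots[:4]:
            ys, xs = np.nonzero(lab == p.plot_id)
            assert np.hypot(xs.mean() - p.center_px[0], ys.mean() - p.center_px[1]) < 2.0

    def test_rotate_back_preserves_canopy(self):
        """30 deg out and back: vegetation IoU with the original stays high
        (bilinear resampling loses only a thin boundary band)."""
        cfg = FieldConfig(n_ranges=3, n_beds=4, gsd_cm=1.0, seed=1)
        ortho, dsm, truth = generate_field(cfg)
        o2, d2, t2 = rotate_field(ortho, dsm, truth, 30.0)
        o3, _, _ = rotate_field(o2, d2, t2, 330.0)
        m0 = vegetation_index(ortho.values).mask
        m3 = vegetation_index(o3.values).mask
        H, W = m0.shape
        H3, W3 = m3.shape
        y0, x0 = (H3 - H) // 2, (W3 - W) // 2
        assert iou(m0, m3[y0 : y0 + H, x0 : x0 + W]) >= 0.98

    def test_orientation_updated(self, small_field):
        _, ortho, dsm, truth = small_field
        _, _, t2 = rotate_field(ortho, dsm, truth, 25.0)
        diff = abs(t2.orientation_deg - (truth.orientation_deg - 25.0)) % 180
        assert min(diff, 180 - diff) < 1e-6
        assert t2.applied_rotation_deg == pytest.approx(25.0)
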