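"""Hough bed-line detection and plot delineation."""

import numpy as np
import pytest

from canoplot.geodata import BOX_SIZE, RasterGrid
from canoplot.gridding import BedLine, delineate_plots, detect_bed_lines, extract_patches


def _ndsm_with_stripes(shape=(300, 400), ys=(100, 200), depth=-0.05, thickness=3):
    values = np.zeros(shape)
    for y in ys:
        values[y : y + thickness, :] = depth
    return RasterGrid(values)


class TestDetectBedLines:
    def test_two_stripes_found_at_their_rows(self):
        ndsm = _ndsm_with_stripes()
        lines = detect_bed_lines(ndsm, merge_dist_px=40)
        assert len(lines) == 2
        assert lines[0].y == pytest.approx(101, abs=2)
        assert lines[1].y == pytest.approx(201, abs=2)
        assert all(l.support > 0 for l in lines)

    def test_accumulator_oracle(self):
        """Peak support equals the direct pixel count on the stripe row."""
        ndsm = _ndsm_with_stripes(ys=(150,), thickness=1)
        lines = detect_bed_lines(ndsm, merge_dist_px=40)
        assert len(lines) == 1
        assert lines[0].support == pytest.approx(400, rel=0.05)

    def test_no_negative_values_is_error(self):
        with pytest.raises(RuntimeError, match="threshold"):
            detect_bed_lines(RasterGrid(np.zeros((50, 50))))

    def test_tilted_stripe_within_angle_window(self):
        values = np.zeros((300, 400))
        xs = np.arange(400)
        ys = np.round(150 + np.tan(np.deg2rad(1.0)) * (xs - 200)).astype(int)
        for x, y in zip(xs, ys):
            values[y - 1 : y + 2, x] = -0.05
        lines = detect_bed_lines(RasterGrid(values), merge_dist_px=60)
        assert len(lines) == 1
        assert lines[0].y == pytest.approx(150, abs=3)

    def test_roi_excludes_outside_votes(self):
        ndsm = _ndsm_with_stripes(ys=(50, 250))
        lines = detect_bed_lines(ndsm, merge_dist_px=40, roi=(0, 400, 0, 150))
        assert len(lines) == 1 and lines[0].y == pytest.approx(51, abs=2)


def _labels_grid(shape=(500, 700), centers=((150, 150), (150, 450), (350, 150), (350, 450))):
    labels = np.zeros(shape, np.int32)
    for i, (cy, cx) in enumerate(centers, start=1):
        labels[cy - 20 : cy + 20, cx - 30 : cx + 30] = i
    return labels


class TestDelineatePlots:
    def test_grid_of_cells_yields_records(self):
        labels = _labels_grid()
        lines = [BedLine(y=50, support=10), BedLine(y=250, support=10), BedLine(y=450, support=10)]
        plots = delineate_plots([(0, 300), (300, 700)], lines, labels)
        assert len(plots) == 4
        assert [(p.bed_idx, p.range_idx) for p in plots] == [(0, 0), (0, 1), (1, 0), (1, 1)]
        assert [p.plot_id for p in plots] == [1, 2, 3, 4]

    def test_center_of_mass_inside_cell(self):
        labels = _labels_grid()
        lines = [BedLine(y=50, support=1), BedLine(y=250, support=1), BedLine(y=450, support=1)]
        plots = delineate_plots([(0, 300), (300, 700)], lines, labels)
        assert plots[0].center == (149.5, 149.5)

    def test_empty_cell_missing_plot(self):
        labels = _labels_grid(centers=((150, 150), (150, 450), (350, 450)))
        lines = [BedLine(y=50, support=1), BedLine(y=250, support=1), BedLine(y=450, support=1)]
        plots = delineate_plots([(0, 300), (300, 700)], lines, labels)
        assert len(plots) == 3

    def test_single_row_flag(self):
        labels = np.zeros((500, 300), np.int32)
        labels[100:130, 100:200] = 1  # only one row in the upper half of the cell
        lines = [BedLine(y=50, support=1), BedLine(y=250, support=1)]
        plots = delineate_plots([(0, 300)], lines, labels)
        assert len(plots) == 1 and plots[0].single_row and plots[0].occupied_half == "top"

    def test_bbox_clamped_inside_raster(self):
        labels = np.zeros((400, 400), np.int32)
        labels[100:140, 30:70] = 1  # center ~50 px from the left edge
        lines = [BedLine(y=50, support=1), BedLine(y=250, support=1)]
        plots = delineate_plots([(0, 400)], lines, labels)
        (p,) = plots
        assert p.bbox[0] == 0  # shifted inward, still BOX_SIZE wide
        assert p.bbox[0] + BOX_SIZE <= 400

    def test_requires_two_lines_and_one_range(self):
        with pytest.raises(ValueError):
            delineate_plots([(0, 10)], [BedLine(y=5, support=1)], np.zeros((10, 10), np.int32))
        with pytest.raises(ValueError):
            delineate_plots([], [BedLine(y=1, support=1), BedLine(y=9, support=1)],
                            np.zeros((10, 10), np.int32))

    def test_mask_pixel_assignment_is_partition(self, segmented_field):
        """Every labeled pixel belongs to exactly one delineated plot cell."""
        cfg, ortho, dsm, truth, veg, layout, labels = segmented_field
        from canoplot.terrain import build_dtm, compute_ndsm, sample_terrain_points

        samples = sample_terrain_points(labels, dsm, offset_px=50, veg_mask=veg.mask)
        dtm = build_dtm(samples, dsm.shape, cfg.gsd_cm)
        ndsm = compute_ndsm(dsm, dtm)
        rows = [y for ys in layout.row_ys for y in ys]
        roi = (layout.range_intervals[0][0], layout.range_intervals[-1][1],
               int(min(rows) - 91), int(max(rows) + 91) + 1)
        lines = detect_bed_lines(ndsm, roi=roi)
        plots = delineate_plots(layout.range_intervals, lines, labels)
        assert len(plots) == len(truth.plots)
        seen = set()
        for p in plots:
            assert p.mask_label not in seen
            seen.add(p.mask_label)


class TestExtractPatches:
    def test_patch_shapes_and_alignment(self, segmented_field):
        cfg, ortho, dsm, truth, veg, layout, labels = segmented_field
        from canoplot.gridding import BedLine

        lines = [BedLine(y=250.0, support=1), BedLine(y=432.0, support=1)]
        plots = delineate_plots(layout.range_intervals, lines, labels)
        patches = extract_patches(ortho, dsm, plots)
        for p, patch in zip(plots, patches):
            assert patch.rgb.shape == (224, 224, 3)
            assert patch.ndsm.shape == (224, 224)
            assert patch.plot_id == p.plot_id
            assert 0 <= patch.center_y < 224
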