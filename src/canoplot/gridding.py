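"""Bed-boundary detection and two-row plot delineation.

Wheel tracks between raised beds sit below the interpolated bed-top terrain,
so they appear as negative values in the nDSM. Thresholding those pixels and
running a Hough transform restricted to near-horizontal lines yields one
line per bed boundary; the lines combined with the range intervals define a
grid of candidate plot cells. Each cell holding at least one segmented row
mask becomes a plot: its center is the center of mass of the mask pixels in
the cell, and a 224 x 224 crop box is centered there (shifted inward at the
raster edge so crops stay inside real data).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.transform import hough_line, hough_line_peaks

from .geodata import BOX_SIZE, PlotRecord, RasterGrid

logger = logging.getLogger(__name__)

__all__ = ["BedLine", "detect_bed_lines", "delineate_plots", "extract_patches"]


@dataclass(frozen=True)
class BedLine:
    y: float  # row coordinate at the image center column
    support: int  # accumulator votes

    def __post_init__(self) -> None:
        if self.support <= 0:
            raise ValueError("bed line must have positive support")


def detect_bed_lines(
    ndsm: RasterGrid,
    depth_threshold_m: float = 0.01,
    angle_window_deg: float = 2.0,
    min_support: int | None = None,
    merge_dist_px: float | None = None,
    bed_width_m: float = 1.82,
    roi: tuple[int, int, int, int] | None = None,
) -> list[BedLine]:
    """Detect bed-boundary lines from negative nDSM values.

    Pixels with nDSM < -``depth_threshold_m`` vote in a Hough accumulator
    restricted to lines within ``angle_window_deg`` of horizontal. Peaks
    above ``min_support`` (default: 10 % of the raster width) are merged when
    closer than half a bed width and returned sorted by y. ``roi``
    (x0, x1, y0, y1) limits voting to the trial area: outside the terrain
    samples' convex hull the DTM is an extrapolation and spurious negative
    values are common, so callers should pass the field extent.
    """
    values = ndsm.values
    low = np.where(np.isfinite(values), values, 0.0) < -depth_threshold_m
    if roi is not None:
        x0r, x1r, y0r, y1r = roi
        keep = np.zeros_like(low)
        keep[max(y0r, 0) : y1r, max(x0r, 0) : x1r] = True
        low &= keep
    if not low.any():
        raise RuntimeError(
            "no pixels below the depth threshold; lower depth_threshold_m or "
            "delineate from the known bed pitch"
        )
    H, W = low.shape
    if min_support is None:
        min_support = max(int(0.10 * W), 10)
    if merge_dist_px is None:
        merge_dist_px = 0.5 * bed_width_m * 100.0 / ndsm.gsd_cm

    theta = np.deg2rad(np.arange(90.0 - angle_window_deg, 90.0 + angle_window_deg + 1e-9, 0.25))
    acc, thetas, rhos = hough_line(low, theta=theta)
    x_c = (W - 1) / 2.0
    # suppress within half a bed pitch in rho across the whole angle window:
    # one peak per boundary, the horizontal line with the most votes
    _, peak_thetas, peak_rhos = hough_line_peaks(
        acc, thetas, rhos, threshold=min_support,
        min_distance=max(int(merge_dist_px), 1), min_angle=len(theta),
        num_peaks=np.inf,
    )
    raw: list[tuple[float, int]] = []
    for th, rho in zip(peak_thetas, peak_rhos):
        y = (rho - x_c * np.cos(th)) / np.sin(th)
        if -merge_dist_px <= y <= H + merge_dist_px:
            ti = int(np.argmin(np.abs(thetas - th)))
            ri = int(np.argmin(np.abs(rhos - rho)))
            raw.append((float(y), int(acc[ri, ti])))
    if not raw:
        raise RuntimeError("Hough transform found no bed-boundary lines; adjust thresholds")
    # centroid-linkage clustering, strongest peaks first: weak peaks from
    # tilted lines attach to the nearest strong boundary instead of chaining
    # adjacent boundaries together
    raw.sort(key=lambda p: p[1], reverse=True)
    clusters: list[list[float]] = []  # [weighted y sum, support sum]
    for y, s in raw:
        for cl in clusters:
            if abs(y - cl[0] / cl[1]) < merge_dist_px:
                cl[0] += y * s
                cl[1] += s
                break
        else:
            clusters.append([y * s, float(s)])
    lines = [BedLine(y=cl[0] / cl[1], support=int(cl[1])) for cl in clusters]
    return sorted(lines, key=lambda line: line.y)


def delineate_plots(
    range_intervals: list[tuple[int, int]],
    bed_lines: list[BedLine],
    row_label_raster: np.ndarray,
) -> list[PlotRecord]:
    """Combine range intervals and bed lines into two-row plot records.

    Cells between consecutive bed lines crossed with range intervals are
    scanned bed-major (then range left to right); a cell with no mask pixels
    is a missing plot and produces no record. ``single_row`` marks cells
    containing exactly one row label; ``occupied_half`` records which half of
    the cell that row occupies.
    """
    if len(bed_lines) < 2:
        raise ValueError("need at least 2 bed lines")
    if not range_intervals:
        raise ValueError("need at least 1 range interval")
    labels = np.asarray(row_label_raster)
    H, W = labels.shape
    records: list[PlotRecord] = []
    plot_id = 0
    ys = sorted(line.y for line in bed_lines)
    for bed_idx, (y_lo, y_hi) in enumerate(zip(ys[:-1], ys[1:])):
        r0 = max(int(np.ceil(y_lo)), 0)
        r1 = min(int(np.floor(y_hi)) + 1, H)
        if r1 <= r0:
            continue
        for range_idx, (x0, x1) in enumerate(range_intervals):
            cell = labels[r0:r1, x0:x1]
            rows_px, cols_px = np.nonzero(cell)
            if rows_px.size == 0:
                logger.info("empty cell bed %d range %d: missing plot", bed_idx, range_idx)
                continue
            plot_id += 1
            cy = r0 + rows_px.mean()
            cx = x0 + cols_px.mean()
            bx = int(np.clip(round(cx) - BOX_SIZE // 2, 0, max(W - BOX_SIZE, 0)))
            by = int(np.clip(round(cy) - BOX_SIZE // 2, 0, max(H - BOX_SIZE, 0)))
            present = np.unique(cell[rows_px, cols_px])
            single = len(present) == 1
            occupied = None
            if single:
                occupied = "top" if cy < (y_lo + y_hi) / 2 else "bottom"
            records.append(
                PlotRecord(
                    plot_id=plot_id,
                    range_idx=range_idx,
                    bed_idx=bed_idx,
                    center=(float(cx), float(cy)),
                    bbox=(bx, by),
                    mask_label=int(present[0]),
                    single_row=single,
                    occupied_half=occupied,
                    cell_y=(float(y_lo), float(y_hi)),
                )
            )
    return records


def extract_patches(
    ortho: RasterGrid,
    ndsm: RasterGrid,
    plots: list[PlotRecord],
) -> list["PlotPatch"]:
    """Crop the 224 x 224 RGB and nDSM patches for each plot."""
    from .traits import PlotPatch

    rgb = np.moveaxis(ortho.values, 0, -1)
    nd = ndsm.values
    patches = []
    for p in plots:
        x0, y0 = p.bbox
        patch_rgb = rgb[y0 : y0 + BOX_SIZE, x0 : x0 + BOX_SIZE]
        patch_nd = nd[y0 : y0 + BOX_SIZE, x0 : x0 + BOX_SIZE].astype(np.float64)
        cell = None
        if p.cell_y is not None:
            cell = (p.cell_y[0] - y0, p.cell_y[1] - y0)
        patches.append(
            PlotPatch(
                rgb=np.ascontiguousarray(patch_rgb),
                ndsm=patch_nd,
                center_y=float(p.center[1] - y0),
                plot_id=p.plot_id,
                single_row=p.single_row,
                occupied_half=p.occupied_half,
                cell_y=cell,
            )
        )
    return patches
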