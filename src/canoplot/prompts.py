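"""Range/row detection from vegetation profiles and prompt-driven plot masks.

Crop ranges are the columns of plots separated by bare-soil alleys: summing
vegetation pixels (ExG-ExR > 0) down each image column yields a profile whose
valleys are the alleys; valley midpoints split the image into range
intervals. Within each range, summing vegetation across rows yields peaks at
the plant rows. The vegetation centroid at each (range, row) crossing is a
provisional plot centroid, used as a foreground point prompt with the
nearest neighbouring centroids as background points.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import signal

logger = logging.getLogger(__name__)

__all__ = [
    "VegetationMap",
    "RowLayout",
    "vegetation_index",
    "detect_ranges",
    "detect_rows",
    "build_layout",
    "make_prompts",
    "segment_rows",
]


@dataclass
class VegetationMap:
    """Per-pixel ExG-ExR score and the derived binary vegetation mask."""

    score: np.ndarray
    mask: np.ndarray


@dataclass
class RowLayout:
    """Detected ranges, per-range row positions and provisional centroids."""

    range_intervals: list[tuple[int, int]]
    row_ys: list[list[float]]  # one list per range interval
    centroids: list[tuple[float, float, int, int]]  # (x, y, range_idx, row_idx)


def vegetation_index(rgb: np.ndarray) -> VegetationMap:
    """Excess-Green minus Excess-Red index from chromatic coordinates.

    With r, g, b = R/(R+G+B), ...: ExG = 2g - r - b and ExR = 1.4 r - g;
    the score is ExG - ExR and pixels with R+G+B = 0 score 0 (non-vegetation).
    Vegetation is score > 0.
    """
    arr = np.asarray(rgb)
    if arr.ndim != 3:
        raise ValueError("expected a 3-band image")
    if arr.shape[0] == 3 and arr.shape[-1] != 3:
        arr = np.moveaxis(arr, 0, -1)
    arr = arr.astype(np.float64)
    total = arr.sum(axis=-1)
    safe = np.where(total > 0, total, 1.0)
    r = arr[..., 0] / safe
    g = arr[..., 1] / safe
    b = arr[..., 2] / safe
    exg = 2.0 * g - r - b
    exr = 1.4 * r - g
    score = exg - exr
    score[total == 0] = 0.0
    return VegetationMap(score=score.astype(np.float32), mask=score > 0)


def _smooth(profile: np.ndarray, width: int) -> np.ndarray:
    width = max(int(width), 1)
    kernel = np.ones(width) / width
    return np.convolve(profile.astype(float), kernel, mode="same")


def detect_ranges(
    veg: VegetationMap,
    valley_frac: float = 0.1,
    smooth_px: int = 1,
) -> list[tuple[int, int]]:
    """Split the image into range x-intervals at vegetation-profile valleys.

    Maximal runs where the smoothed column-sum profile falls below
    ``valley_frac`` of its maximum are valleys; interval boundaries sit at
    interior valley midpoints, with the first/last boundary clamped to the
    image edges. Returns half-open ``[x_start, x_end)`` intervals containing
    vegetation; empty when the mask is empty.
    """
    profile = veg.mask.sum(axis=0)
    if profile.max() == 0:
        return []
    smoothed = _smooth(profile, smooth_px)
    low = smoothed < valley_frac * smoothed.max()
    W = len(profile)
    boundaries = [0]
    in_run = False
    start = 0
    for x in range(W + 1):
        is_low = low[x] if x < W else False
        if is_low and not in_run:
            in_run, start = True, x
        elif not is_low and in_run:
            in_run = False
            if start > 0 and x < W:  # interior valley; edge valleys clamp
                boundaries.append((start + x) // 2)
    boundaries.append(W)
    intervals = []
    for lo, hi in zip(boundaries[:-1], boundaries[1:]):
        if hi > lo and profile[lo:hi].max() > 0:
            intervals.append((lo, hi))
    return intervals


def detect_rows(
    veg: VegetationMap,
    interval: tuple[int, int],
    peak_frac: float = 0.3,
    smooth_px: int = 1,
    min_separation_px: int = 1,
) -> list[float]:
    """Row y-positions inside one range interval.

    Local maxima of the smoothed row-sum profile above ``peak_frac`` of its
    maximum, at least ``min_separation_px`` apart (half the expected row
    spacing), sorted by y. May be empty.
    """
    x0, x1 = interval
    profile = veg.mask[:, x0:x1].sum(axis=1)
    if profile.max() == 0:
        return []
    smoothed = _smooth(profile, smooth_px)
    peaks, _ = signal.find_peaks(
        smoothed,
        height=peak_frac * smoothed.max(),
        distance=max(int(min_separation_px), 1),
    )
    return [float(p) for p in sorted(peaks)]


def build_layout(
    veg: VegetationMap,
    gsd_cm: float,
    row_spacing_m: float = 0.91,
    valley_frac: float = 0.1,
    peak_frac: float = 0.3,
) -> RowLayout:
    """Detect ranges and rows and place provisional plot centroids.

    The smoothing window is a quarter of the expected row spacing in pixels;
    each centroid is the vegetation centroid within its (range, row) cell so
    that the foreground prompt lands on canopy even for edge ranges whose
    interval includes image margin.
    """
    spacing_px = row_spacing_m * 100.0 / gsd_cm
    smooth_px = max(int(round(0.25 * spacing_px)), 1)
    intervals = detect_ranges(veg, valley_frac=valley_frac, smooth_px=smooth_px)
    row_ys: list[list[float]] = []
    centroids: list[tuple[float, float, int, int]] = []
    half_band = max(int(round(0.45 * spacing_px)), 1)
    for ri, (x0, x1) in enumerate(intervals):
        ys = detect_rows(
            veg,
            (x0, x1),
            peak_frac=peak_frac,
            smooth_px=smooth_px,
            min_separation_px=int(round(0.5 * spacing_px)),
        )
        row_ys.append(ys)
        for yi, y in enumerate(ys):
            y_lo = max(int(y) - half_band, 0)
            y_hi = min(int(y) + half_band + 1, veg.mask.shape[0])
            band = veg.mask[y_lo:y_hi, x0:x1]
            ys_b, xs_b = np.nonzero(band)
            if xs_b.size == 0:
                logger.warning("no vegetation at range %d row %d; centroid skipped", ri, yi)
                continue
            centroids.append(
                (float(x0 + xs_b.mean()), float(y_lo + ys_b.mean()), ri, yi)
            )
    return RowLayout(range_intervals=intervals, row_ys=row_ys, centroids=centroids)


def make_prompts(
    layout: RowLayout,
    target: tuple[float, float, int, int],
    k_neighbors: int = 4,
) -> tuple[list[tuple[float, float]], list[tuple[float, float]]]:
    """Foreground/background point prompts for one provisional centroid.

    The target centroid is the foreground point; the ``k_neighbors`` nearest
    other centroids (typically the rows above/below and adjacent ranges) are
    background points.
    """
    if target not in layout.centroids:
        raise ValueError("target is not one of the layout centroids")
    tx, ty = target[0], target[1]
    others = [c for c in layout.centroids if c is not target and c != target]
    others.sort(key=lambda c: math.hypot(c[0] - tx, c[1] - ty))
    bg = [(c[0], c[1]) for c in others[:k_neighbors]]
    return [(tx, ty)], bg


def segment_rows(
    backend,
    rgb: np.ndarray,
    layout: RowLayout,
    k_neighbors: int = 4,
) -> np.ndarray:
    """Prompt the backend once per centroid and build a label raster.

    Each returned mask is clipped to its centroid's range interval; a pixel
    claimed by several prompts is assigned to the nearest claiming centroid.
    Labels are consecutive positive integers in centroid order; a centroid
    whose prompt yields an empty mask is logged as a missing row.
    """
    if not layout.centroids:
        raise ValueError("layout has no centroids")
    shape = rgb.shape[-2:] if rgb.shape[0] == 3 else rgb.shape[:2]
    labels = np.zeros(shape, dtype=np.int32)
    centroid_of: dict[int, tuple[float, float]] = {}
    for i, cent in enumerate(layout.centroids):
        lab = i + 1
        fg, bg = make_prompts(layout, cent, k_neighbors=k_neighbors)
        mask = backend.prompt_mask(rgb, fg, bg)
        x0, x1 = layout.range_intervals[cent[2]]
        mask = mask.copy()
        mask[:, :x0] = False
        mask[:, x1:] = False
        if not mask.any():
            logger.warning("empty mask for centroid %s; row flagged missing", cent)
            continue
        centroid_of[lab] = (cent[0], cent[1])
        contested = mask & (labels > 0)
        labels[mask & ~contested] = lab
        if contested.any():
            ys, xs = np.nonzero(contested)
            for other in np.unique(labels[ys, xs]):
                ox, oy = centroid_of[int(other)]
                sel = labels[ys, xs] == other
                d_new = (xs[sel] - cent[0]) ** 2 + (ys[sel] - cent[1]) ** 2
                d_old = (xs[sel] - ox) ** 2 + (ys[sel] - oy) ** 2
                win = d_new < d_old
                labels[ys[sel][win], xs[sel][win]] = lab
    return labels
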