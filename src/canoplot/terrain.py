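"""Plot-local terrain sampling, Delaunay DTM interpolation, and the nDSM.

Terrain elevations are read from the DSM at two points per segmented mask,
placed on opposite sides of the mask along the bed (left/right of its
bounding box) at the mask's centroid row. Because plots sit on raised beds,
these points land on the bare bed top in the alleys, so the interpolated
terrain surface represents the bed surface and the nDSM isolates canopy
height; wheel tracks between beds come out negative in the nDSM, which is
what the bed-line detector consumes.

The DTM is the piecewise-linear interpolant over the Delaunay triangulation
of the sample points; pixels outside the convex hull take the nearest
sample's elevation. Linear interpolation reproduces any affine terrain
exactly, and by construction the nDSM is zero at every sample point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator

from .geodata import RasterGrid

logger = logging.getLogger(__name__)

__all__ = ["TerrainSample", "sample_terrain_points", "build_dtm", "compute_ndsm"]


@dataclass
class TerrainSample:
    point: tuple[int, int]  # (x, y) pixel
    elevation_m: float
    plot_id: int  # owning mask label
    side: str  # "left" or "right"
    flagged: bool = False  # clamped against the raster edge


def sample_terrain_points(
    label_raster: np.ndarray,
    dsm: RasterGrid,
    offset_px: int,
    veg_mask: np.ndarray | None = None,
    median3: bool = False,
) -> list[TerrainSample]:
    """Two terrain samples per labeled mask, beside its bounding box.

    Points start ``offset_px`` outside the mask bbox at the mask centroid
    row, are clamped inside the raster (flagged when clamping collapses a
    side onto the bbox), and are nudged outward by up to ``offset_px`` extra
    pixels if they land on vegetation. A sample reading NaN from the DSM is
    dropped with a warning. ``median3`` reads a 3x3 median instead of the
    single pixel.
    """
    labels = np.asarray(label_raster)
    if labels.shape != dsm.shape:
        raise ValueError("label raster and DSM are not co-registered")
    H, W = labels.shape
    values = dsm.values
    objects = ndimage.find_objects(labels)
    samples: list[TerrainSample] = []
    for lab, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        ys, xs = np.nonzero(labels[sl] == lab)
        if xs.size == 0:
            continue
        y_c = int(round(sl[0].start + ys.mean()))
        x_min = sl[1].start
        x_max = sl[1].stop - 1
        for side, x_raw in (("left", x_min - offset_px), ("right", x_max + offset_px)):
            flagged = False
            x = int(x_raw)
            if x < 0 or x >= W:
                x = min(max(x, 0), W - 1)
                flagged = True
            if veg_mask is not None:
                step = -1 if side == "left" else 1
                budget = offset_px
                while budget > 0 and 0 <= x < W and veg_mask[y_c, x]:
                    x += step
                    budget -= 1
                x = min(max(x, 0), W - 1)
            if median3:
                y0, y1 = max(y_c - 1, 0), min(y_c + 2, H)
                x0, x1 = max(x - 1, 0), min(x + 2, W)
                elev = float(np.nanmedian(values[y0:y1, x0:x1]))
            else:
                elev = float(values[y_c, x])
            if not np.isfinite(elev):
                logger.warning("DSM nodata at terrain sample (%d, %d); dropped", x, y_c)
                continue
            samples.append(
                TerrainSample(point=(x, y_c), elevation_m=elev, plot_id=lab, side=side, flagged=flagged)
            )
    return samples


def build_dtm(samples: list[TerrainSample], shape: tuple[int, int], gsd_cm: float = 1.0) -> RasterGrid:
    """Interpolate a terrain raster from the samples.

    Piecewise-linear over the Delaunay triangulation inside the convex hull
    of the sample points; nearest-sample elevation outside it. Requires at
    least 3 non-collinear samples.
    """
    if len(samples) < 3:
        raise ValueError("need at least 3 terrain samples")
    pts = np.array([s.point for s in samples], dtype=float)
    z = np.array([s.elevation_m for s in samples])
    # de-duplicate coincident points (nudging can collide)
    _, keep = np.unique(pts, axis=0, return_index=True)
    pts, z = pts[np.sort(keep)], z[np.sort(keep)]
    if len(pts) < 3 or np.linalg.matrix_rank(pts - pts[0], tol=1e-9) < 2:
        raise ValueError("terrain samples are collinear; cannot triangulate")
    H, W = shape
    xs, ys = np.meshgrid(np.arange(W, dtype=float), np.arange(H, dtype=float))
    query = np.column_stack([xs.ravel(), ys.ravel()])
    linear = LinearNDInterpolator(pts, z)
    dtm = linear(query)
    outside = np.isnan(dtm)
    if outside.any():
        nearest = NearestNDInterpolator(pts, z)
        dtm[outside] = nearest(query[outside])
    return RasterGrid(dtm.reshape(H, W), gsd_cm=gsd_cm)


def compute_ndsm(dsm: RasterGrid, dtm: RasterGrid) -> RasterGrid:
    """Per-pixel DSM minus DTM; NaN (nodata) propagates."""
    if dsm.shape != dtm.shape:
        raise ValueError(f"shape mismatch: DSM {dsm.shape} vs DTM {dtm.shape}")
    return RasterGrid(
        dsm.values.astype(np.float64) - dtm.values.astype(np.float64),
        gsd_cm=dsm.gsd_cm,
        origin=dsm.origin,
    )
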