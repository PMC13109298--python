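"""Field localization: boundary mask, oriented rectangle, orientation, and
rotation of the scene to axis alignment.

The experimental field is assumed roughly centered in the orthomosaic (as
flight plans are designed): candidate masks from the segmentation backend are
filtered to those whose bounding-box center lies within a few pixels of the
image center at the working (resized) resolution, and the survivor with the
best mean of predicted-IoU and stability score becomes the field mask.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull
from shapely.geometry import MultiPoint

from .backends import BackendParams
from .geodata import RasterGrid
from .prompts import vegetation_index

logger = logging.getLogger(__name__)

__all__ = [
    "FieldRegion",
    "prepare_image",
    "mask_min_rect",
    "estimate_orientation",
    "locate_field",
    "rotate_to_axis",
]


@dataclass
class FieldRegion:
    mask: np.ndarray  # bool, full resolution
    min_rect: np.ndarray  # (4, 2) corners, full-resolution pixel coords
    orientation_deg: float  # [0, 180)
    center_dist_px: float  # candidate center distance used in filtering
    score: float  # mean of predicted IoU and stability
    n_candidates: int


def prepare_image(ortho: RasterGrid | np.ndarray) -> tuple[np.ndarray, float]:
    """Resize so the longest side is exactly 1024 px, preserving aspect.

    Returns the resized RGB array (3, h, w) and the scale factor mapping
    resized coordinates back to full resolution. Short-side size rounds to
    the nearest integer.
    """
    from skimage.transform import resize

    values = ortho.values if isinstance(ortho, RasterGrid) else np.asarray(ortho)
    if values.ndim != 3 or values.shape[0] != 3:
        raise ValueError("expected a (3, H, W) RGB raster")
    H, W = values.shape[1:]
    long_side = max(H, W)
    if long_side == 1024:
        return values, 1.0
    scale = long_side / 1024.0
    if H >= W:
        new_h, new_w = 1024, int(round(W / scale))
    else:
        new_h, new_w = int(round(H / scale)), 1024
    out = resize(
        values, (3, new_h, new_w), order=1, preserve_range=True,
        anti_aliasing=scale > 1.0,
    )
    return np.clip(out, 0, 255).astype(np.uint8), scale


def mask_min_rect(mask: np.ndarray) -> np.ndarray:
    """Corners of the minimum-area oriented rectangle enclosing a mask.

    Uses the per-row extreme pixels of the mask (which contain its convex
    hull) so the hull stays cheap on megapixel masks.
    """
    mask = np.asarray(mask, dtype=bool)
    rows = np.any(mask, axis=1).nonzero()[0]
    if rows.size == 0:
        raise ValueError("mask is empty")
    pts = []
    for r in rows:
        cols = np.nonzero(mask[r])[0]
        pts.append((cols[0], r))
        if cols[-1] != cols[0]:
            pts.append((cols[-1], r))
    pts = np.asarray(pts, dtype=float)
    if len(pts) < 3:
        raise ValueError("mask has fewer than 3 boundary pixels")
    try:
        hull = pts[ConvexHull(pts).vertices]
    except Exception:  # collinear degenerate
        raise ValueError("mask is degenerate (collinear pixels)")
    rect = MultiPoint([tuple(p) for p in hull]).minimum_rotated_rectangle
    corners = np.asarray(rect.exterior.coords[:4], dtype=float)
    return corners


def _principal_angle(mask: np.ndarray) -> float:
    """First-principal-component angle of mask pixel coordinates, [0, 180)."""
    ys, xs = np.nonzero(mask)
    x = xs - xs.mean()
    y = ys - ys.mean()
    cov = np.array([[x @ x, x @ y], [x @ y, y @ y]]) / len(xs)
    evals, evecs = np.linalg.eigh(cov)
    v = evecs[:, np.argmax(evals)]
    return math.degrees(math.atan2(v[1], v[0])) % 180.0


def estimate_orientation(mask: np.ndarray) -> float:
    """Orientation of a mask in degrees, in [0, 180).

    The angle of the long side of the minimum-area enclosing rectangle
    (equivalently, the first principal axis of the mask pixels; both are
    computed and a disagreement beyond 2 degrees is logged). A square mask is
    a degenerate tie: the smaller of the two side angles is returned. Angles
    are reported modulo 180 since a field has no front/back.
    """
    if np.count_nonzero(mask) < 3:
        raise ValueError("mask must contain at least 3 pixels")
    rect = mask_min_rect(mask)
    e1 = rect[1] - rect[0]
    e2 = rect[2] - rect[1]
    l1, l2 = np.hypot(*e1), np.hypot(*e2)
    a1 = math.degrees(math.atan2(e1[1], e1[0])) % 180.0
    a2 = math.degrees(math.atan2(e2[1], e2[0])) % 180.0
    if abs(l1 - l2) <= 1e-9 * max(l1, l2) + 1e-6:
        angle = min(a1, a2)
    else:
        angle = a1 if l1 > l2 else a2
    pca = _principal_angle(mask)
    diff = abs(angle - pca) % 180.0
    diff = min(diff, 180.0 - diff)
    if diff > 2.0 and min(l1, l2) / max(l1, l2) < 0.95:
        logger.warning(
            "min-rect orientation %.2f and PCA orientation %.2f disagree by %.2f deg",
            angle, pca, diff,
        )
    return angle % 180.0


def locate_field(
    ortho: RasterGrid,
    backend,
    params: BackendParams | None = None,
    center_radius_px: float = 5.0,
) -> FieldRegion:
    """Identify the field mask, its oriented rectangle and orientation.

    The orthomosaic is resized (longest side 1024 px), candidate masks are
    generated, candidates whose bounding-box center lies farther than
    ``center_radius_px`` (resized coordinates) from the image center are
    excluded, and the survivor with the highest mean of predicted IoU and
    stability is selected and upscaled to full resolution.
    """
    resized, scale = prepare_image(ortho)
    candidates = backend.auto_masks(resized, params or BackendParams())
    h, w = resized.shape[-2:]
    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    survivors = []
    for cand in candidates:
        d = float(np.hypot(*(np.array(cand.centroid) - center)))
        if d <= center_radius_px:
            survivors.append((cand, d))
    if not survivors:
        raise RuntimeError(
            f"no candidate mask within {center_radius_px} px of the image center "
            f"({len(candidates)} candidates total); try a larger center_radius_px"
        )
    best, best_d = max(survivors, key=lambda cd: (cd[0].predicted_iou + cd[0].stability) / 2)
    H, W = ortho.shape
    if scale != 1.0:
        mask_full = ndimage.zoom(
            best.mask, (H / best.mask.shape[0], W / best.mask.shape[1]), order=0,
            grid_mode=True, mode="grid-constant",
        )
        mask_full = mask_full[:H, :W]
    else:
        mask_full = best.mask
    rect = mask_min_rect(mask_full)
    return FieldRegion(
        mask=mask_full,
        min_rect=rect,
        orientation_deg=estimate_orientation(mask_full),
        center_dist_px=best_d,
        score=(best.predicted_iou + best.stability) / 2,
        n_candidates=len(candidates),
    )


def _rotate_pair(
    ortho: RasterGrid, dsm: RasterGrid | None, angle_deg: float
) -> tuple[RasterGrid, RasterGrid | None, dict]:
    """Rotate ortho (and DSM) by ``angle_deg`` about the image center with a
    shared transform; DSM is NaN-filled outside the original footprint."""
    h_in, w_in = ortho.shape
    if angle_deg % 360.0 == 0.0:
        ident = dict(angle_deg=0.0, c_in=((w_in - 1) / 2, (h_in - 1) / 2),
                     c_out=((w_in - 1) / 2, (h_in - 1) / 2))
        return ortho, dsm, ident
    # fill out-of-footprint RGB with the border's median color (bare soil)
    fill = [int(np.median(ortho.values[c, 0, :])) for c in range(3)]
    bands = [
        ndimage.rotate(
            ortho.values[c], angle_deg, reshape=True, order=1,
            mode="constant", cval=fill[c], prefilter=False,
        )
        for c in range(3)
    ]
    ortho_rot = ortho.copy_with(np.clip(np.stack(bands), 0, 255).astype(np.uint8))
    dsm_rot = None
    if dsm is not None:
        dsm_rot = dsm.copy_with(
            ndimage.rotate(
                dsm.values.astype(np.float64), angle_deg, reshape=True, order=1,
                mode="constant", cval=np.nan, prefilter=False,
            )
        )
    h_out, w_out = ortho_rot.shape
    transform = dict(
        angle_deg=angle_deg,
        c_in=((w_in - 1) / 2.0, (h_in - 1) / 2.0),
        c_out=((w_out - 1) / 2.0, (h_out - 1) / 2.0),
    )
    return ortho_rot, dsm_rot, transform


def transform_points(points: np.ndarray, transform: dict) -> np.ndarray:
    """Apply a rotation transform (as returned by ``rotate_to_axis``) to
    (x, y) pixel points."""
    t = math.radians(transform["angle_deg"])
    rot = np.array([[math.cos(t), -math.sin(t)], [math.sin(t), math.cos(t)]])
    pts = np.asarray(points, dtype=float)
    return (pts - np.asarray(transform["c_in"])) @ rot + np.asarray(transform["c_out"])


def rotate_to_axis(
    ortho: RasterGrid,
    dsm: RasterGrid | None,
    region: FieldRegion,
    canonicalize: bool = True,
) -> tuple[RasterGrid, RasterGrid | None, dict]:
    """Rotate both rasters by the negative field orientation so the trial
    grid is axis-parallel.

    With ``canonicalize``, the alley signature decides which image axis
    carries the bare-soil alleys afterwards: alleys are far wider than the
    inter-row gaps, so the vegetation profile with the larger empty fraction
    marks the across-range axis, and the scene is rotated a further 90 deg if
    the alleys came out horizontal. This keeps ranges vertical and bed lines
    horizontal regardless of whether the field is longest along or across
    the beds.
    """
    # minimal rotation that cancels the orientation (long side -> horizontal);
    # applying angle a through the raster rotation lowers orientation by a
    angle = (region.orientation_deg + 90.0) % 180.0 - 90.0
    if canonicalize:
        veg = vegetation_index(ortho.values)
        probe = ndimage.rotate(
            veg.mask.astype(np.uint8), angle, reshape=True, order=0,
            mode="constant", cval=0, prefilter=False,
        ).astype(bool)
        if _alleys_are_horizontal(probe):
            angle += 90.0
    # rotations are equivalent mod 180 for the trial grid; use the smallest
    angle = (angle + 90.0) % 180.0 - 90.0
    return _rotate_pair(ortho, dsm, angle)


def _alleys_are_horizontal(veg_mask: np.ndarray) -> bool:
    """True when the wide bare-soil alleys run across (not down) the image.

    Alleys are several times wider than the gaps between plant rows, so the
    vegetation profile along the across-range axis has a much larger
    near-empty fraction; compare both axes within the vegetated core.
    """
    cols = veg_mask.sum(axis=0)
    rows = veg_mask.sum(axis=1)
    nz_c = np.nonzero(cols)[0]
    nz_r = np.nonzero(rows)[0]
    if not (nz_c.size and nz_r.size):
        return False
    core_c = cols[nz_c[0] : nz_c[-1] + 1]
    core_r = rows[nz_r[0] : nz_r[-1] + 1]
    empty_cols = np.mean(core_c < 0.05 * core_c.max())
    empty_rows = np.mean(core_r < 0.05 * core_r.max())
    return bool(empty_rows > empty_cols)
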