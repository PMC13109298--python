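"""Synthetic raised-bed trial generator with full ground truth.

Emulates a two-row plot arrangement on raised beds: beds run horizontally
across the scene with two plant rows per bed (0.91 m apart on a 1.82 m bed),
plots repeat along the bed with 2 m bare-soil alleys between planted
segments, and narrow wheel-track furrows (default 5 cm deep) mark every bed
boundary. Each surviving plot is rendered as two green canopy blobs on a soil
background; the DSM is the terrain surface plus the rendered canopy height
field plus optional Gaussian noise.

Canopy height follows a truncated normal calibrated so that the *realized*
distribution matches the reference field statistics (mean 24.8 cm, SD
6.37 cm, range 16-40 cm). Growth-habit classes differ in canopy footprint
and height profile (bunch: compact and domed; spreading: wide and flat);
mainstem-prominence classes differ by a central height ridge along the row.

All randomness flows from ``FieldConfig.seed``; identical configs produce
bit-identical rasters and truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
from scipy import ndimage, optimize, stats

from .geodata import RasterGrid

__all__ = ["FieldConfig", "TruthPlot", "SyntheticTruth", "generate_field", "rotate_field"]

SOIL_RGB = (118, 98, 76)
CANOPY_RGB = (56, 112, 48)

# canopy footprint semi-axes (m) and dome exponents per growth-habit class
_GH_SHAPE = {
    "bunch": dict(a=0.33, b=0.30, flatness=1.0, dome=0.8),
    "spreading": dict(a=0.46, b=0.40, flatness=2.0, dome=0.30),
}
_SIZE_JITTER_M = 0.02  # SD of per-plot semi-axis jitter, clipped at 2 SD
_MP_RIDGE_DEPTH = 0.14  # off-ridge height reduction for "apparent" mainstems
_MP_RIDGE_SIGMA_M = 0.08


@dataclass(frozen=True)
class FieldConfig:
    """Layout, trait-distribution and terrain parameters of a synthetic trial."""

    n_ranges: int = 5
    n_beds: int = 8
    bed_width_m: float = 1.82
    row_spacing_m: float = 0.91
    plot_len_m: float = 0.5
    alley_m: float = 2.0
    gsd_cm: float = 1.0
    margin_m: float = 2.5
    ch_mean_cm: float = 24.8
    ch_sd_cm: float = 6.37
    ch_range_cm: tuple[float, float] = (16.0, 40.0)
    p_spreading: float = 0.508
    p_mp_apparent: float = 0.657
    base_elev_m: float = 50.0
    terrain_slope: tuple[float, float] = (0.0, 0.0)  # m elevation per m of x, y
    furrow_depth_m: float = 0.05
    furrow_width_m: float = 0.30
    noise_sd_m: float = 0.0
    missing_plot_rate: float = 0.0
    single_row_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("bed_width_m", "row_spacing_m", "plot_len_m", "alley_m", "gsd_cm", "margin_m"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.n_ranges < 1 or self.n_beds < 1:
            raise ValueError("field too small: need at least one range and one bed")
        lo, hi = self.ch_range_cm
        if not lo < hi:
            raise ValueError("ch_range_cm must satisfy min < max")
        for name in ("missing_plot_rate", "single_row_rate", "p_spreading", "p_mp_apparent"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")

    @property
    def range_pitch_m(self) -> float:
        return self.plot_len_m + self.alley_m

    @property
    def gsd_m(self) -> float:
        return self.gsd_cm / 100.0


@dataclass
class TruthPlot:
    plot_id: int
    range_idx: int
    bed_idx: int
    center_px: tuple[float, float]
    polygon_px: np.ndarray  # (4, 2) cell corners, pixel coords
    ch_cm: float
    gh: str
    mp: str
    single_row: bool


@dataclass
class SyntheticTruth:
    """Ground truth: plot polygons/masks, trait labels, field extent, terrain."""

    plots: list[TruthPlot]
    label_raster: np.ndarray  # (H, W) int32, plot_id per canopy pixel, 0 = background
    field_rect_px: np.ndarray  # (4, 2) corners of the planted-extent rectangle
    orientation_deg: float  # angle of the rect's long side, [0, 180)
    applied_rotation_deg: float
    terrain: object  # callable (x_px, y_px) -> elevation in m
    config: FieldConfig

    @property
    def canopy_mask(self) -> np.ndarray:
        return self.label_raster > 0

    def plot_at(self, x: float, y: float) -> TruthPlot | None:
        """The plot whose truth polygon contains pixel (x, y), if any."""
        from shapely.geometry import Point, Polygon

        pt = Point(x, y)
        for p in self.plots:
            if Polygon(p.polygon_px).covers(pt):
                return p
        return None


@lru_cache(maxsize=8)
def _truncnorm_parent_params(
    mean: float, sd: float, lo: float, hi: float
) -> tuple[float, float]:
    """Parent (mu, sigma) of a truncated normal whose truncated moments match."""

    def residual(p):
        mu, sigma = p
        sigma = abs(sigma)
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return [m - mean, math.sqrt(v) - sd]

    sol = optimize.fsolve(residual, [mean, sd], full_output=False)
    mu, sigma = float(sol[0]), abs(float(sol[1]))
    return mu, sigma


def sample_canopy_heights(config: FieldConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw per-plot canopy heights (cm) from the calibrated truncated normal."""
    lo, hi = config.ch_range_cm
    mu, sigma = _truncnorm_parent_params(config.ch_mean_cm, config.ch_sd_cm, lo, hi)
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    return stats.truncnorm.rvs(a, b, loc=mu, scale=sigma, size=n, random_state=rng)


def _rect_orientation_deg(rect: np.ndarray) -> float:
    """Angle in [0, 180) of the long side of a 4-corner rectangle (px coords)."""
    rect = np.asarray(rect, dtype=float)
    e1 = rect[1] - rect[0]
    e2 = rect[2] - rect[1]
    long_edge = e1 if np.hypot(*e1) >= np.hypot(*e2) else e2
    ang = math.degrees(math.atan2(long_edge[1], long_edge[0])) % 180.0
    return ang


def generate_field(config: FieldConfig) -> tuple[RasterGrid, RasterGrid, SyntheticTruth]:
    """Render a synthetic trial: (orthomosaic, DSM, ground truth).

    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    gsd = config.gsd_m
    pitch_x = config.range_pitch_m
    pitch_y = config.bed_width_m

    field_w = config.n_ranges * pitch_x
    field_h = config.n_beds * pitch_y
    x0_m, y0_m = config.margin_m, config.margin_m
    W = int(round((field_w + 2 * config.margin_m) / gsd))
    H = int(round((field_h + 2 * config.margin_m) / gsd))

    # ---- per-plot attributes (drawn before any pixel noise, fixed order) ----
    n_plots = config.n_ranges * config.n_beds
    heights_cm = sample_canopy_heights(config, n_plots, rng)
    gh_draw = rng.random(n_plots) < config.p_spreading
    mp_draw = rng.random(n_plots) < config.p_mp_apparent
    dropped = rng.random(n_plots) < config.missing_plot_rate
    single = rng.random(n_plots) < config.single_row_rate
    single_top = rng.random(n_plots) < 0.5
    size_jit = np.clip(
        rng.normal(0.0, _SIZE_JITTER_M, size=(n_plots, 2)),
        -2 * _SIZE_JITTER_M,
        2 * _SIZE_JITTER_M,
    )

    # ---- terrain ----
    sx, sy = config.terrain_slope
    xs_m = np.arange(W) * gsd
    ys_m = np.arange(H) * gsd
    terrain = config.base_elev_m + sx * xs_m[None, :] + sy * ys_m[:, None]
    terrain = np.broadcast_to(terrain, (H, W)).astype(np.float64).copy()
    # wheel-track furrows on every bed boundary (n_beds + 1 tracks), spanning
    # the field plus half an alley on each side
    fx0 = int(round((x0_m - config.alley_m / 2) / gsd))
    fx1 = int(round((x0_m + field_w + config.alley_m / 2) / gsd))
    fx0, fx1 = max(fx0, 0), min(fx1, W)
    half_fw = config.furrow_width_m / 2
    for j in range(config.n_beds + 1):
        yb = y0_m + j * pitch_y
        r0 = max(int(round((yb - half_fw) / gsd)), 0)
        r1 = min(int(round((yb + half_fw) / gsd)), H)
        terrain[r0:r1, fx0:fx1] -= config.furrow_depth_m

    # ---- canopy rendering ----
    canopy_h = np.zeros((H, W), dtype=np.float64)
    labels = np.zeros((H, W), dtype=np.int32)
    plots: list[TruthPlot] = []
    half_row = config.row_spacing_m / 2

    idx = 0
    plot_id = 0
    for b in range(config.n_beds):
        bed_top = y0_m + b * pitch_y
        cy_bed = bed_top + pitch_y / 2
        for r in range(config.n_ranges):
            attrs = (heights_cm[idx], gh_draw[idx], mp_draw[idx], dropped[idx],
                     single[idx], single_top[idx], size_jit[idx])
            idx += 1
            ch_cm, is_spreading, is_apparent, is_dropped, is_single, top, jit = attrs
            if is_dropped:
                continue
            plot_id += 1
            gh = "spreading" if is_spreading else "bunch"
            mp = "apparent" if is_apparent else "not_apparent"
            shape = _GH_SHAPE[gh]
            a_m = shape["a"] + jit[0]
            b_m = shape["b"] + jit[1]
            cx = x0_m + (r + 0.5) * pitch_x
            row_ys = [cy_bed - half_row, cy_bed + half_row]
            if is_single:
                row_ys = [row_ys[0]] if top else [row_ys[1]]
            for ry in row_ys:
                _render_blob(
                    canopy_h, labels, plot_id, cx, ry, a_m, b_m,
                    shape["flatness"], shape["dome"], ch_cm / 100.0,
                    is_apparent, gsd,
                )
            cell = np.array(
                [
                    [x0_m + r * pitch_x, bed_top],
                    [x0_m + (r + 1) * pitch_x, bed_top],
                    [x0_m + (r + 1) * pitch_x, bed_top + pitch_y],
                    [x0_m + r * pitch_x, bed_top + pitch_y],
                ]
            ) / gsd
            plots.append(
                TruthPlot(
                    plot_id=plot_id,
                    range_idx=r,
                    bed_idx=b,
                    center_px=(cx / gsd, cy_bed / gsd),
                    polygon_px=cell,
                    ch_cm=float(ch_cm),
                    gh=gh,
                    mp=mp,
                    single_row=bool(is_single),
                )
            )

    if not plots:
        raise ValueError("all plots were dropped; lower missing_plot_rate")

    # ---- rasters ----
    ortho = np.empty((3, H, W), dtype=np.int16)
    for c, base in enumerate(SOIL_RGB):
        ortho[c] = base
    ortho += rng.integers(-8, 9, size=(3, H, W), dtype=np.int16)
    canopy = labels > 0
    jitter = rng.integers(-10, 11, size=(3, int(canopy.sum())), dtype=np.int16)
    for c, base in enumerate(CANOPY_RGB):
        chan = ortho[c]
        chan[canopy] = base + jitter[c]
    ortho = np.clip(ortho, 0, 255).astype(np.uint8)

    dsm = terrain + canopy_h
    if config.noise_sd_m > 0:
        dsm = dsm + rng.normal(0.0, config.noise_sd_m, size=(H, W))

    rows = np.any(canopy, axis=1).nonzero()[0]
    cols = np.any(canopy, axis=0).nonzero()[0]
    rect = np.array(
        [
            [cols[0], rows[0]],
            [cols[-1], rows[0]],
            [cols[-1], rows[-1]],
            [cols[0], rows[-1]],
        ],
        dtype=float,
    )

    def terrain_at(x_px, y_px):
        x_px = np.asarray(x_px, dtype=float)
        y_px = np.asarray(y_px, dtype=float)
        xi = np.clip(np.round(x_px).astype(int), 0, W - 1)
        yi = np.clip(np.round(y_px).astype(int), 0, H - 1)
        return terrain[yi, xi]

    truth = SyntheticTruth(
        plots=plots,
        label_raster=labels,
        field_rect_px=rect,
        orientation_deg=_rect_orientation_deg(rect),
        applied_rotation_deg=0.0,
        terrain=terrain_at,
        config=config,
    )
    ortho_grid = RasterGrid(ortho, gsd_cm=config.gsd_cm)
    dsm_grid = RasterGrid(dsm.astype(np.float64), gsd_cm=config.gsd_cm)
    return ortho_grid, dsm_grid, truth


def _render_blob(
    canopy_h: np.ndarray,
    labels: np.ndarray,
    plot_id: int,
    cx_m: float,
    cy_m: float,
    a_m: float,
    b_m: float,
    flatness: float,
    dome: float,
    ch_m: float,
    mp_apparent: bool,
    gsd: float,
) -> None:
    """Render one row's canopy bump into the height and label rasters.

    The footprint is an ellipse; the height profile is ``(1 - v^flatness)^dome``
    of the squared normalized radius v, so the peak equals ``ch_m`` exactly.
    Apparent mainstems get a ridge along the row: off-ridge height is reduced
    by up to ``_MP_RIDGE_DEPTH`` with the peak height unchanged.
    """
    H, W = canopy_h.shape
    x_lo = max(int((cx_m - a_m) / gsd) - 1, 0)
    x_hi = min(int((cx_m + a_m) / gsd) + 2, W)
    y_lo = max(int((cy_m - b_m) / gsd) - 1, 0)
    y_hi = min(int((cy_m + b_m) / gsd) + 2, H)
    if x_lo >= x_hi or y_lo >= y_hi:
        return
    xs = np.arange(x_lo, x_hi) * gsd - cx_m
    ys = np.arange(y_lo, y_hi) * gsd - cy_m
    dx, dy = np.meshgrid(xs, ys)
    v = (dx / a_m) ** 2 + (dy / b_m) ** 2
    inside = v < 1.0
    profile = np.zeros_like(v)
    profile[inside] = (1.0 - v[inside] ** flatness) ** dome
    if mp_apparent:
        ridge = 1.0 - _MP_RIDGE_DEPTH * (1.0 - np.exp(-((dy / _MP_RIDGE_SIGMA_M) ** 2)))
        profile *= ridge
    h = ch_m * profile
    win_h = canopy_h[y_lo:y_hi, x_lo:x_hi]
    win_l = labels[y_lo:y_hi, x_lo:x_hi]
    np.maximum(win_h, h, out=win_h)
    win_l[inside] = plot_id


def rotate_field(
    ortho: RasterGrid,
    dsm: RasterGrid,
    truth: SyntheticTruth,
    angle_deg: float,
) -> tuple[RasterGrid, RasterGrid, SyntheticTruth]:
    """Rotate the scene about the image center, expanding the canvas.

    Out-of-footprint pixels are filled with the flat soil color in the
    orthomosaic and NaN in the DSM. Truth polygons, centers and the field
    rectangle are mapped by the same transform; the label raster is rotated
    with nearest-neighbour resampling.
    """
    if not 0.0 <= angle_deg < 360.0:
        angle_deg = angle_deg % 360.0
    if angle_deg == 0.0:
        return ortho, dsm, truth

    bands = [
        ndimage.rotate(
            ortho.values[c], angle_deg, reshape=True, order=1,
            mode="constant", cval=SOIL_RGB[c], prefilter=False,
        )
        for c in range(3)
    ]
    ortho_rot = np.clip(np.stack(bands), 0, 255).astype(np.uint8)
    dsm_rot = ndimage.rotate(
        dsm.values.astype(np.float64), angle_deg, reshape=True, order=1,
        mode="constant", cval=np.nan, prefilter=False,
    )
    labels_rot = ndimage.rotate(
        truth.label_raster, angle_deg, reshape=True, order=0,
        mode="constant", cval=0, prefilter=False,
    )

    h_in, w_in = ortho.shape
    h_out, w_out = ortho_rot.shape[-2:]
    c_in = np.array([(w_in - 1) / 2, (h_in - 1) / 2])
    c_out = np.array([(w_out - 1) / 2, (h_out - 1) / 2])
    # scipy's rotate maps output->input with R(theta) in (row, col) order;
    # the forward pixel map in (x, y) order is the inverse rotation below.
    t = math.radians(angle_deg)
    rot = np.array([[math.cos(t), -math.sin(t)], [math.sin(t), math.cos(t)]])

    def fwd(pts: np.ndarray) -> np.ndarray:
        return (np.asarray(pts, dtype=float) - c_in) @ rot + c_out

    plots = [
        replace(
            p,
            center_px=tuple(fwd(np.array(p.center_px))),
            polygon_px=fwd(p.polygon_px),
        )
        for p in truth.plots
    ]
    rect = fwd(truth.field_rect_px)

    base_terrain = truth.terrain

    def terrain_at(x_px, y_px):
        pts = np.stack(
            [np.asarray(x_px, dtype=float), np.asarray(y_px, dtype=float)], axis=-1
        )
        src = (pts - c_out) @ rot.T + c_in
        return base_terrain(src[..., 0], src[..., 1])

    new_truth = SyntheticTruth(
        plots=plots,
        label_raster=labels_rot,
        field_rect_px=rect,
        orientation_deg=_rect_orientation_deg(rect),
        applied_rotation_deg=(truth.applied_rotation_deg + angle_deg) % 180.0,
        terrain=terrain_at,
        config=truth.config,
    )
    return (
        ortho.copy_with(ortho_rot),
        dsm.copy_with(dsm_rot),
        new_truth,
    )
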