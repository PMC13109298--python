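"""Core raster/vector data types and file I/O shared by all pipeline stages.

Rasters are plain TIFFs (single-band float32 for elevation products, 3-band
uint8 for orthomosaics) with the pixel size, world origin and nodata sentinel
stored as JSON metadata in the image description. Outputs live in a local
coordinate system: pixel (0, 0) maps to ``origin``, x grows with columns and
world y decreases with rows (north-up). Plot boundaries are exported as ESRI
shapefiles; trait tables as CSV.

Pixel convention: 0-based (x = column, y = row), pixel centers at integer
coordinates; 224 px bounding boxes are half-open ``[x0, x0+224) x [y0, y0+224)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import _shp

__all__ = [
    "BOX_SIZE",
    "RasterGrid",
    "PlotRecord",
    "read_raster",
    "write_raster",
    "write_plot_shapefile",
    "read_plot_shapefile",
    "make_trait_table",
    "write_trait_table",
]

BOX_SIZE = 224  # side of the per-plot crop, px


@dataclass
class RasterGrid:
    """A pixel grid with scale and a pixel-to-world affine mapping.

    ``values`` is ``(3, H, W)`` uint8 for RGB orthomosaics or ``(H, W)``
    float (meters) for elevation rasters. ``gsd_cm`` is the ground sampling
    distance in cm per pixel; ``origin`` the world coordinate of pixel (0, 0).
    Missing elevation is NaN (``nodata``).
    """

    values: np.ndarray
    gsd_cm: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: float = float("nan")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim not in (2, 3):
            raise ValueError("raster must be 2-D (elevation) or 3-D (RGB)")
        if self.values.ndim == 3 and self.values.shape[0] != 3:
            raise ValueError("RGB raster must have shape (3, H, W)")
        if min(self.shape) < 1:
            raise ValueError("raster must have at least one pixel")
        if not self.gsd_cm > 0:
            raise ValueError("gsd_cm must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[-2:]

    @property
    def is_rgb(self) -> bool:
        return self.values.ndim == 3

    @property
    def gsd_m(self) -> float:
        return self.gsd_cm / 100.0

    def pixel_to_world(self, x, y):
        """Map pixel coordinates to world coordinates (north-up)."""
        return (
            self.origin[0] + np.asarray(x, dtype=float) * self.gsd_m,
            self.origin[1] - np.asarray(y, dtype=float) * self.gsd_m,
        )

    def world_to_pixel(self, wx, wy):
        return (
            (np.asarray(wx, dtype=float) - self.origin[0]) / self.gsd_m,
            (self.origin[1] - np.asarray(wy, dtype=float)) / self.gsd_m,
        )

    def copy_with(self, values: np.ndarray) -> "RasterGrid":
        return replace(self, values=values)


@dataclass
class PlotRecord:
    """One two-row experimental plot located on the axis-aligned rasters."""

    plot_id: int
    range_idx: int
    bed_idx: int
    center: tuple[float, float]
    bbox: tuple[int, int]  # top-left (x0, y0) of the BOX_SIZE crop
    mask_label: int = 0
    single_row: bool = False
    occupied_half: str | None = None  # "top"/"bottom" for single-row plots
    cell_y: tuple[float, float] | None = None  # bed-line bounds of the plot

    @property
    def bbox_corners(self) -> list[tuple[int, int]]:
        x0, y0 = self.bbox
        return [(x0, y0), (x0 + BOX_SIZE, y0), (x0 + BOX_SIZE, y0 + BOX_SIZE), (x0, y0 + BOX_SIZE)]

    def __post_init__(self) -> None:
        x0, y0 = self.bbox
        cx, cy = self.center
        if not (x0 <= cx < x0 + BOX_SIZE and y0 <= cy < y0 + BOX_SIZE):
            raise ValueError(f"plot {self.plot_id}: center {self.center} outside bbox")


def read_raster(path: str | Path, gsd_cm: float | None = None) -> RasterGrid:
    """Read a single- or three-band TIFF raster.

    Scale/origin/nodata are restored from the file's JSON metadata when the
    file was written by :func:`write_raster`; otherwise a default origin of
    (0, 0) is assumed and ``gsd_cm`` (default 1.0) must be supplied by the
    caller, matching non-georeferenced local-coordinate workflows.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        values = tif.asarray()
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    if values.ndim == 3:
        if values.shape[-1] == 3:  # stored H, W, 3
            values = np.moveaxis(values, -1, 0)
        if values.shape[0] != 3:
            raise ValueError(f"{path}: band count {values.shape[0]} not in {{1, 3}}")
    elif values.ndim != 2:
        raise ValueError(f"{path}: unsupported raster layout {values.shape}")
    grid = RasterGrid(
        values=values,
        gsd_cm=float(meta.get("gsd_cm", gsd_cm if gsd_cm is not None else 1.0)),
        origin=tuple(meta.get("origin", (0.0, 0.0))),
    )
    meta_nodata = meta.get("nodata")
    if meta_nodata is not None and not grid.is_rgb and not np.isnan(meta_nodata):
        vals = grid.values.astype(np.float32, copy=True)
        vals[vals == meta_nodata] = np.nan
        grid.values = vals
    return grid


def write_raster(raster: RasterGrid, path: str | Path) -> None:
    """Write a raster as TIFF with scale/origin metadata."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    values = raster.values
    if raster.is_rgb:
        data = np.moveaxis(np.asarray(values, dtype=np.uint8), 0, -1)
    else:
        data = np.asarray(values, dtype=np.float32)
    tifffile.imwrite(
        path,
        data,
        metadata={
            "gsd_cm": raster.gsd_cm,
            "origin": list(raster.origin),
            "nodata": None if raster.is_rgb else float("nan"),
        },
    )


_PLOT_FIELDS = [
    ("plot_id", "N", 10, 0),
    ("range_idx", "N", 6, 0),
    ("bed_idx", "N", 6, 0),
    ("single_row", "L", 1, 0),
]


def write_plot_shapefile(
    plots: list[PlotRecord],
    gsd_cm: float,
    origin: tuple[float, float],
    path: str | Path,
) -> None:
    """Write one polygon per plot (bbox corners in world coordinates).

    Attributes: plot_id, range_idx, bed_idx, single_row. Companion .shx/.dbf
    files are written next to the .shp.
    """
    if not plots:
        raise ValueError("no plots to write")
    ref = RasterGrid(np.zeros((1, 1)), gsd_cm=gsd_cm, origin=origin)
    polygons = []
    records = []
    for p in plots:
        ring = [tuple(map(float, ref.pixel_to_world(x, y))) for x, y in p.bbox_corners]
        polygons.append(ring)
        records.append((p.plot_id, p.range_idx, p.bed_idx, p.single_row))
    _shp.write_polygon_shapefile(path, polygons, _PLOT_FIELDS, records)


def read_plot_shapefile(path: str | Path) -> tuple[list[list[tuple[float, float]]], list[dict]]:
    """Read plot polygons (world coords) and their attribute dicts."""
    return _shp.read_polygon_shapefile(path)


def make_trait_table(rows: list[dict]) -> pd.DataFrame:
    """Assemble a per-plot trait table (one row per plot_id).

    Columns: plot_id, ch_cm, ch_stat, gh, mp. ``gh`` is 'bunch'/'spreading',
    ``mp`` 'apparent'/'not_apparent'; either may be missing (NaN) when no
    classifier was run.
    """
    df = pd.DataFrame(rows)
    required = ["plot_id", "ch_cm", "ch_stat"]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"trait table missing column {col!r}")
    if df["plot_id"].duplicated().any():
        raise ValueError("duplicate plot_id in trait table")
    if (df["ch_cm"] < 0).any():
        raise ValueError("canopy height must be non-negative")
    for col in ("gh", "mp"):
        if col not in df.columns:
            df[col] = pd.NA
    return df[["plot_id", "ch_cm", "ch_stat", "gh", "mp"]]


def write_trait_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
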