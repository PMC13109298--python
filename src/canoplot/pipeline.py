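"""End-to-end pipeline: field -> prompts -> rows -> nDSM -> plots -> traits.

Stages run in a fixed order with per-stage wall-clock logging; intermediate
products (field shapefile, label rasters, DTM/nDSM, plot shapefile, crops,
trait table) are written to the output directory together with a JSON report
of stage runtimes, counts and parameters. With the classical backend and a
fixed seed the whole run is deterministic.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import geodata, gridding, locate, prompts, terrain
from .backends import BackendParams, get_backend
from .geodata import RasterGrid

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

STAGES = ["find-field", "segment-plots", "build-ndsm", "delineate", "extract-traits"]


@dataclass
class PipelineConfig:
    """Declarative configuration for a full run; defaults follow the
    automated-orthomosaic protocol wherever it states a parameter."""

    ortho_path: str | None = None
    dsm_path: str | None = None
    out_dir: str = "canoplot_out"
    backend: str = "classical"
    checkpoint_path: str | None = None
    backend_params: BackendParams = field(default_factory=BackendParams)
    center_radius_px: float = 5.0
    rotate_to_axis: bool = True
    row_spacing_m: float = 0.91
    bed_width_m: float = 1.82
    alley_m: float = 2.0
    valley_frac: float = 0.1
    peak_frac: float = 0.3
    k_neighbors: int = 4
    terrain_offset_px: int | None = None  # default: 0.25 x alley width in px
    terrain_median3: bool = False
    depth_threshold_m: float = 0.01
    angle_window_deg: float = 2.0
    ch_stat: str = "max"
    gsd_cm: float | None = None  # override when rasters carry no metadata
    seed: int = 0
    save_rasters: bool = True


@dataclass
class PipelineResult:
    plots: list
    traits: "object"
    report: dict
    out_dir: Path
    ndsm: RasterGrid
    patches: list
    transform: dict | None = None  # input -> working pixel coords, if rotated


def run_pipeline(
    config: PipelineConfig,
    ortho: RasterGrid | None = None,
    dsm: RasterGrid | None = None,
) -> PipelineResult:
    """Run all stages; any stage failure aborts with the stage name."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if ortho is None:
        if config.ortho_path is None:
            raise ValueError("missing input: provide an orthomosaic (path or raster)")
        ortho = geodata.read_raster(config.ortho_path, gsd_cm=config.gsd_cm)
    if dsm is None:
        if config.dsm_path is None:
            raise ValueError("missing input: provide a DSM (path or raster)")
        dsm = geodata.read_raster(config.dsm_path, gsd_cm=config.gsd_cm)
    if ortho.shape != dsm.shape:
        raise ValueError("orthomosaic and DSM must share shape")

    backend = get_backend(
        config.backend,
        **({"checkpoint_path": config.checkpoint_path} if config.backend == "foundation" else {}),
    )
    report: dict = {"stages": [], "parameters": _jsonable(asdict(config))}

    def stage(name: str):
        class _Timer:
            def __enter__(self_t):
                self_t.t0 = time.perf_counter()
                logger.info("stage %s ...", name)
                return self_t

            def __exit__(self_t, exc_type, exc, tb):
                dt = time.perf_counter() - self_t.t0
                if exc is not None:
                    raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
                report["stages"].append({"name": name, "seconds": round(dt, 3)})
                logger.info("stage %s done in %.2f s", name, dt)

        return _Timer()

    with stage("find-field"):
        region = locate.locate_field(
            ortho, backend, config.backend_params, config.center_radius_px
        )
        report["orientation_deg"] = region.orientation_deg
        report["field_score"] = region.score
        report["n_candidates"] = region.n_candidates
        transform = None
        if config.rotate_to_axis:
            ortho, dsm, transform = locate.rotate_to_axis(ortho, dsm, region)
            report["axis_rotation_deg"] = transform["angle_deg"]
            backend = get_backend(config.backend) if config.backend == "classical" else backend

    with stage("segment-plots"):
        veg = prompts.vegetation_index(ortho.values)
        layout = prompts.build_layout(
            veg, ortho.gsd_cm, row_spacing_m=config.row_spacing_m,
            valley_frac=config.valley_frac, peak_frac=config.peak_frac,
        )
        labels = prompts.segment_rows(backend, ortho.values, layout, config.k_neighbors)
        report["n_ranges"] = len(layout.range_intervals)
        report["n_row_masks"] = int(len(np.unique(labels)) - 1)

    with stage("build-ndsm"):
        offset = config.terrain_offset_px
        if offset is None:
            offset = max(int(round(0.25 * config.alley_m * 100.0 / ortho.gsd_cm)), 1)
        samples = terrain.sample_terrain_points(
            labels, dsm, offset, veg_mask=veg.mask, median3=config.terrain_median3
        )
        dtm = terrain.build_dtm(samples, dsm.shape, gsd_cm=dsm.gsd_cm)
        ndsm = terrain.compute_ndsm(dsm, dtm)
        report["n_terrain_samples"] = len(samples)

    with stage("delineate"):
        all_rows = [y for ys in layout.row_ys for y in ys]
        pad = 0.5 * config.bed_width_m * 100.0 / ortho.gsd_cm
        roi = (
            layout.range_intervals[0][0],
            layout.range_intervals[-1][1],
            int(min(all_rows) - pad),
            int(max(all_rows) + pad) + 1,
        )
        lines = gridding.detect_bed_lines(
            ndsm, depth_threshold_m=config.depth_threshold_m,
            angle_window_deg=config.angle_window_deg, bed_width_m=config.bed_width_m,
            roi=roi,
        )
        plots = gridding.delineate_plots(layout.range_intervals, lines, labels)
        if not plots:
            raise RuntimeError("no plots delineated")
        report["n_bed_lines"] = len(lines)
        report["n_plots"] = len(plots)

    with stage("extract-traits"):
        from .traits import extract_canopy_height

        patches = gridding.extract_patches(ortho, ndsm, plots)
        rows = [
            dict(
                plot_id=p.plot_id,
                ch_cm=extract_canopy_height(patch, stat=config.ch_stat),
                ch_stat=config.ch_stat,
            )
            for p, patch in zip(plots, patches)
        ]
        traits_df = geodata.make_trait_table(rows)

    if config.save_rasters:
        geodata.write_raster(dtm, out_dir / "dtm.tif")
        geodata.write_raster(ndsm, out_dir / "ndsm.tif")
        geodata.write_raster(
            RasterGrid(labels.astype(np.float32), gsd_cm=ortho.gsd_cm), out_dir / "row_labels.tif"
        )
    geodata.write_plot_shapefile(plots, ortho.gsd_cm, ortho.origin, out_dir / "plots.shp")
    geodata.write_trait_table(traits_df, out_dir / "traits.csv")
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return PipelineResult(
        plots=plots, traits=traits_df, report=report, out_dir=out_dir,
        ndsm=ndsm, patches=patches, transform=transform,
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, Path):
        return str(obj)
    return obj
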