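"""End-to-end orchestration: scenes -> differences -> clustering -> report.

Stage order mirrors the mapping methodology: ingest co-registered pre/post
scenes, compute the selected vegetation-index pair and their differences,
segment burned/unburned with bisecting K-means, stratify severity with
K-means, derive slope weights from an optional DEM, and report areas and
severity shares against an optional reference delimitation.

Any stage error aborts with a stage-named message and removes partial
outputs. Runs are deterministic for a fixed config + seed; the report JSON
is byte-identical across repeated runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from . import __version__
from .indices import compute_index, index_difference, screen_indices
from .io_geodata import (
    DEFAULT_BAND_MAP,
    InputError,
    Scene,
    grids_compatible,
    load_vector_mask,
    rasterize_mask,
    read_scene,
    write_raster,
)
from .mapping import SEVERITY_NODATA, map_burned_area, map_severity
from .report import AreaReport, reference_area_from_mask, severity_percentages
from .terrain import slope_weights, weighted_area

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "screen"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Paths and parameters of one mapping run."""

    pre: str
    post: str
    out_dir: str
    dem: str | None = None
    aoi: str | None = None
    reference_delimitation: str | None = None
    band_map: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_BAND_MAP))
    scale_factor: float = 1e-4
    index_pair: tuple[str, str] = ("NDVI", "YNDVI")
    wdrvi_a: float = 0.1
    seed: int = 0
    tol: float = 1e-6
    max_iter: int = 300
    n_trial_bisections: int = 5

    def __post_init__(self) -> None:
        if len(set(self.index_pair)) != 2:
            raise InputError("index_pair must name two distinct indices")


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - rewrap with stage context
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc

        return wrapped

    return deco


@_stage("ingest")
def _load_scenes(cfg: RunConfig) -> tuple[Scene, Scene]:
    pre = read_scene(cfg.pre, cfg.band_map, cfg.scale_factor)
    post = read_scene(cfg.post, cfg.band_map, cfg.scale_factor)
    if not grids_compatible(pre.grid, post.grid):
        raise InputError(
            "pre and post scenes are not co-registered (shape, pixel size or "
            "origin differ); resample upstream before mapping"
        )
    return pre, post


def run_pipeline(cfg: RunConfig) -> tuple[object, object, AreaReport]:
    """Execute the full mapping run; returns (BurnMask, SeverityMap, AreaReport).

    Writes ``burn_mask.tif``, ``severity.tif``, ``slope.tif`` (if a DEM is
    given), ``screening.csv``, ``report.json`` and ``run_log.json`` into
    ``out_dir``.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write(name: str, fn) -> Path:
        path = out_dir / name
        fn(path)
        written.append(path)
        return path

    try:
        pre, post = _load_scenes(cfg)
        grid = pre.grid
        params = {"wdrvi_a": cfg.wdrvi_a}

        aoi_plane = None
        if cfg.aoi is not None:
            aoi_plane = _stage("aoi")(
                lambda: rasterize_mask(load_vector_mask(cfg.aoi, "aoi"), grid)
            )()

        @_stage("indices")
        def _differences():
            diffs = []
            for name in cfg.index_pair:
                d = index_difference(
                    compute_index(pre, name, params), compute_index(post, name, params)
                )
                diffs.append(d)
            return diffs

        d1, d2 = _differences()

        @_stage("screening")
        def _screening(path: Path):
            screen_indices(pre, post, aoi_plane, params).to_csv(path, index=False)

        _write("screening.csv", _screening)

        @_stage("burned-area clustering")
        def _burn():
            return map_burned_area(
                d1,
                d2,
                aoi_plane,
                seed=cfg.seed,
                max_iter=cfg.max_iter,
                tol=cfg.tol,
                n_trial_bisections=cfg.n_trial_bisections,
            )

        mask, burn_clusters = _burn()

        @_stage("severity clustering")
        def _sev():
            return map_severity(
                d1, d2, mask, seed=cfg.seed, max_iter=cfg.max_iter, tol=cfg.tol
            )

        sev, sev_clusters = _sev()

        flags = list(mask.flags)
        weights = None
        if cfg.dem is not None:

            @_stage("terrain")
            def _terrain():
                from .io_geodata import read_raster

                dem_arr, dem_grid, dem_nodata = read_raster(cfg.dem)
                dem = dem_arr[0].astype(float)
                if dem_nodata is not None:
                    dem[dem == dem_nodata] = np.nan
                return slope_weights(dem, dem_grid, grid)

            weights = _terrain()
            flags.extend(weights.flags)
        else:
            flags.append("no_dem_planimetric_areas")

        @_stage("reporting")
        def _report():
            estimated = weighted_area(mask, weights=weights)
            reference = None
            if cfg.reference_delimitation is not None:
                ref_mask = load_vector_mask(
                    cfg.reference_delimitation, "reference_delimitation"
                )
                reference = reference_area_from_mask(ref_mask, grid, weights)
            sev_pct = None
            if sev is not None:
                sev_pct = severity_percentages(sev, weights)
                flags.extend(f for f in sev.flags if f not in flags)
            else:
                flags.append("severity_skipped")
            return AreaReport.build(estimated, reference, sev_pct, flags)

        report = _report()

        @_stage("outputs")
        def _outputs():
            _write("burn_mask.tif", lambda p: write_raster(mask.values, grid, p))
            if sev is not None:
                sev_out = np.where(
                    sev.values == SEVERITY_NODATA, 255, sev.values
                ).astype(np.uint8)
                _write("severity.tif", lambda p: write_raster(sev_out, grid, p, nodata=255))
            if weights is not None:
                _write("slope.tif", lambda p: write_raster(weights.slope, grid, p))
            _write("report.json", lambda p: p.write_text(report.to_json() + "\n"))
            log = {
                "package": "burnmap",
                "version": __version__,
                "seed": cfg.seed,
                "index_pair": list(cfg.index_pair),
                "scale_factor": cfg.scale_factor,
                "wdrvi_a": cfg.wdrvi_a,
                "tol": cfg.tol,
                "max_iter": cfg.max_iter,
                "n_trial_bisections": cfg.n_trial_bisections,
                "burn_cluster_centroids": burn_clusters.centroids.tolist(),
                "burn_cluster_sse": burn_clusters.sse_per_cluster.tolist(),
                "severity_centroids": None
                if sev_clusters is None
                else sev_clusters.centroids.tolist(),
                "flags": report.flags,
            }
            _write(
                "run_log.json",
                lambda p: p.write_text(json.dumps(log, indent=2, sort_keys=True) + "\n"),
            )

        _outputs()
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise

    return mask, sev, report


def screen(cfg: RunConfig):
    """Index screening only: returns the table and writes ``screening.csv``."""
    pre, post = _load_scenes(cfg)
    aoi_plane = None
    if cfg.aoi is not None:
        aoi_plane = rasterize_mask(load_vector_mask(cfg.aoi, "aoi"), pre.grid)
    elif cfg.reference_delimitation is not None:
        aoi_plane = rasterize_mask(
            load_vector_mask(cfg.reference_delimitation, "reference_delimitation"),
            pre.grid,
        )
    table = screen_indices(pre, post, aoi_plane, {"wdrvi_a": cfg.wdrvi_a})
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table.to_csv(out_dir / "screening.csv", index=False)
    return table
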