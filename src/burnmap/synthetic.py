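"""Synthetic pre/post fire scene pairs, ground truth and analytic DEMs.

Every pipeline stage is testable without licensed satellite imagery: the
generator emulates paired 8-band SuperDove-class surface-reflectance scenes
at 3 m containing one contiguous burned region with graded severity, plus a
DEM whose slope (and hence true surface area) is known in closed form.

Construction:

* The burned region is the top ``burned_fraction`` quantile of a
  Gaussian-smoothed random field — taking exactly the top-k pixels, so the
  ground-truth burned pixel count is exact and area tests are sharp.
* Severity rings are concentric: pixels are ranked by distance to the burn
  edge and split into ``n_severity_rings`` equal-count rings, outermost =
  lightest damage, core = destroyed.
* The pre scene is the healthy-vegetation signature everywhere; the post
  scene keeps the healthy signature outside the burn and applies a
  severity-dependent burned signature inside. Independent additive Gaussian
  noise (std ``noise_sigma``, reflectance units) is drawn per scene.

Default signatures give NDVI ≈ 0.75 for healthy vegetation and post-fire
NDVI of {0.30, 0.20, 0.10, 0.00} across the four severity levels, i.e.
dNDVI ≈ 0.45–0.75 inside the burn and ≈ 0 outside. The lowest severity
level is kept well separated from the unburned background so that the
two-cluster SSE optimum in difference space coincides with the true
burned/unburned partition (see docs/methods.md for the analysis).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.ndimage import distance_transform_edt, gaussian_filter

from .io_geodata import BAND_NAMES, GridGeometry, InputError, Scene

__all__ = [
    "ScenarioConfig",
    "GroundTruth",
    "default_signatures",
    "generate_scene_pair",
    "generate_dem",
]

#: Post-fire NDVI levels per severity class (0 = slight .. 3 = destroyed).
POST_FIRE_NDVI = (0.30, 0.20, 0.10, 0.00)

_HEALTHY = {
    "COASTAL_BLUE": 0.03,
    "BLUE": 0.04,
    "GREEN_I": 0.08,
    "GREEN": 0.09,
    "YELLOW": 0.08,
    "RED": 0.08,
    "RED_EDGE": 0.30,
    "NIR": 0.56,
}


def default_signatures() -> dict[str, np.ndarray]:
    """Per-class mean reflectance in the 8-band layout.

    Keys: ``healthy`` plus ``burned_0`` .. ``burned_3``. Burned classes keep
    NIR + RED = 0.64 constant while NDVI drops with severity; the yellow
    band brightens in step with red (char and exposed soil), visible bands
    darken slightly.
    """
    sigs = {"healthy": np.array([_HEALTHY[b] for b in BAND_NAMES])}
    for k, p in enumerate(POST_FIRE_NDVI):
        nir = 0.32 * (1.0 + p)
        red = 0.32 * (1.0 - p)
        yellow = 0.32 * (1.0 - (p + 0.02))
        sig = {
            "COASTAL_BLUE": 0.04,
            "BLUE": 0.05,
            "GREEN_I": 0.07 + 0.01 * k,
            "GREEN": 0.08 + 0.01 * k,
            "YELLOW": yellow,
            "RED": red,
            "RED_EDGE": 0.5 * (red + nir),
            "NIR": nir,
        }
        sigs[f"burned_{k}"] = np.array([sig[b] for b in BAND_NAMES])
    return sigs


@dataclass
class ScenarioConfig:
    """Study conditions for one synthetic fire scenario.

    ``dem_mode`` is one of ``"flat"``, ``("tilted", angle_deg)`` or
    ``("sinusoidal", amplitude_m, wavelength_m)``.
    """

    n_rows: int = 300
    n_cols: int = 300
    pixel_size: float = 3.0
    burned_fraction: float = 0.2
    n_severity_rings: int = 4
    noise_sigma: float = 0.02
    seed: int = 0
    dem_mode: object = "flat"
    dem_pixel_size: float = 30.0
    signatures: Mapping[str, np.ndarray] = field(default_factory=default_signatures)
    origin_x: float = 500_000.0
    origin_y: float = 4_100_000.0
    crs_epsg: int = 32634
    blob_smoothness: float = 0.05  # smoothing length as a fraction of min(n_rows, n_cols)

    def __post_init__(self) -> None:
        if not (0.0 < self.burned_fraction < 1.0):
            raise InputError("burned_fraction must lie in (0, 1)")
        if self.noise_sigma < 0:
            raise InputError("noise_sigma must be non-negative")
        for sig in self.signatures.values():
            arr = np.asarray(sig)
            if arr.shape != (len(BAND_NAMES),) or not ((arr > 0) & (arr < 1)).all():
                raise InputError("signatures must be 8-band reflectances in (0, 1)")
        n_burn = round(self.n_rows * self.n_cols * self.burned_fraction)
        if n_burn < self.n_severity_rings:
            raise InputError("burned_fraction yields fewer pixels than severity rings")

    @property
    def grid(self) -> GridGeometry:
        return GridGeometry(
            n_rows=self.n_rows,
            n_cols=self.n_cols,
            pixel_size_x=self.pixel_size,
            pixel_size_y=self.pixel_size,
            origin_x=self.origin_x,
            origin_y=self.origin_y,
            crs_epsg=self.crs_epsg,
        )


@dataclass
class GroundTruth:
    """What the generator actually drew: mask, severity field, true area."""

    burn_mask: np.ndarray
    severity_field: np.ndarray  # -1 outside the burn
    true_burned_area_ha: float
    true_planimetric_ha: float


def _burn_geometry(cfg: ScenarioConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Contiguous burned blob (exact pixel count) + concentric severity rings."""
    n = cfg.n_rows * cfg.n_cols
    k = round(n * cfg.burned_fraction)
    sigma = max(2.0, cfg.blob_smoothness * min(cfg.n_rows, cfg.n_cols))
    f = gaussian_filter(rng.standard_normal((cfg.n_rows, cfg.n_cols)), sigma)
    flat_order = np.argsort(f, axis=None, kind="stable")
    mask = np.zeros(n, dtype=bool)
    mask[flat_order[-k:]] = True
    mask = mask.reshape(cfg.n_rows, cfg.n_cols)

    dist = distance_transform_edt(mask)
    idx = np.flatnonzero(mask.ravel())
    # rank by edge distance (row-major order breaks ties) -> equal-count rings
    order = idx[np.argsort(dist.ravel()[idx], kind="stable")]
    sev = np.full(n, -1, dtype=np.int16)
    splits = np.array_split(order, cfg.n_severity_rings)
    for ring, members in enumerate(splits):
        sev[members] = ring
    return mask, sev.reshape(cfg.n_rows, cfg.n_cols)


def _analytic_weight_at(cfg: ScenarioConfig, x: np.ndarray) -> np.ndarray:
    """Closed-form 1/cos(slope) of the DEM surface at map x coordinates."""
    mode = cfg.dem_mode
    if mode == "flat":
        return np.ones_like(x)
    kind = mode[0]
    if kind == "tilted":
        theta = math.radians(mode[1])
        if not (0 <= mode[1] < 90):
            raise InputError("tilt angle must lie in [0, 90) degrees")
        return np.full_like(x, 1.0 / math.cos(theta))
    if kind == "sinusoidal":
        amplitude, wavelength = mode[1], mode[2]
        g = amplitude * 2 * math.pi / wavelength * np.cos(2 * math.pi * x / wavelength)
        return np.sqrt(1.0 + g**2)  # 1/cos(arctan|g|)
    raise InputError(f"unknown dem_mode {mode!r}")


def generate_scene_pair(cfg: ScenarioConfig) -> tuple[Scene, Scene, GroundTruth]:
    """Draw a (pre, post, truth) triple; deterministic for a fixed seed."""
    rng = np.random.default_rng(cfg.seed)
    mask, sev = _burn_geometry(cfg, rng)
    grid = cfg.grid
    band_map = {name: i for i, name in enumerate(BAND_NAMES)}

    healthy = np.asarray(cfg.signatures["healthy"])
    pre = np.empty((len(BAND_NAMES), cfg.n_rows, cfg.n_cols))
    pre[:] = healthy[:, None, None]
    post = pre.copy()
    for ring in range(cfg.n_severity_rings):
        # with more rings than signature classes, reuse the nearest class
        sig_key = f"burned_{min(ring, 3)}"
        sig = np.asarray(cfg.signatures[sig_key])
        sel = sev == ring
        post[:, sel] = sig[:, None]

    if cfg.noise_sigma > 0:
        pre = pre + rng.normal(0.0, cfg.noise_sigma, pre.shape)
        post = post + rng.normal(0.0, cfg.noise_sigma, post.shape)

    pre_scene = Scene(grid=grid, bands=pre, band_map=band_map)
    post_scene = Scene(grid=grid, bands=post, band_map=band_map)

    # analytic slope weighting at burned pixel centers
    xw = grid.x_centers()[None, :] * np.ones((cfg.n_rows, 1))
    w = _analytic_weight_at(cfg, xw)
    planimetric = mask.sum() * grid.pixel_area_m2 / 10_000.0
    true_area = float(w[mask].sum()) * grid.pixel_area_m2 / 10_000.0
    truth = GroundTruth(
        burn_mask=mask,
        severity_field=sev,
        true_burned_area_ha=true_area,
        true_planimetric_ha=planimetric,
    )
    return pre_scene, post_scene, truth


def generate_dem(cfg: ScenarioConfig) -> tuple[np.ndarray, GridGeometry, float]:
    """DEM raster covering the scene with a margin + its mean surface factor.

    The DEM grid is coarser than the scene grid (``dem_pixel_size``, default
    30 m, emulating 1-arc-second elevation data) and extends one DEM pixel
    beyond the scene so bilinear resampling has full support. The returned
    factor is the analytic mean of 1/cos(slope) over the scene extent
    (exact for flat and tilted modes; midpoint-rule quadrature at 10,000
    points for the sinusoidal mode).
    """
    scene = cfg.grid
    ps = cfg.dem_pixel_size
    # two-pixel margin: scene pixel centers then interpolate only between
    # interior DEM pixels, clear of the replicated-edge slope artifact
    x0 = scene.origin_x - 2 * ps
    y0 = scene.origin_y + 2 * ps
    width = scene.n_cols * scene.pixel_size_x + 4 * ps
    height = scene.n_rows * scene.pixel_size_y + 4 * ps
    dem_grid = GridGeometry(
        n_rows=math.ceil(height / ps),
        n_cols=math.ceil(width / ps),
        pixel_size_x=ps,
        pixel_size_y=ps,
        origin_x=x0,
        origin_y=y0,
        crs_epsg=cfg.crs_epsg,
    )
    xs = dem_grid.x_centers()[None, :]
    mode = cfg.dem_mode
    if mode == "flat":
        z = np.zeros(dem_grid.shape)
        factor = 1.0
    elif mode[0] == "tilted":
        if not (0 <= mode[1] < 90):
            raise InputError("tilt angle must lie in [0, 90) degrees")
        z = math.tan(math.radians(mode[1])) * (xs - scene.origin_x) * np.ones(
            (dem_grid.n_rows, 1)
        )
        factor = 1.0 / math.cos(math.radians(mode[1]))
    elif mode[0] == "sinusoidal":
        amplitude, wavelength = mode[1], mode[2]
        z = amplitude * np.sin(2 * math.pi * (xs - scene.origin_x) / wavelength) * np.ones(
            (dem_grid.n_rows, 1)
        )
        xq = scene.origin_x + (np.arange(10_000) + 0.5) * (
            scene.n_cols * scene.pixel_size_x / 10_000
        )
        factor = float(_analytic_weight_at(cfg, xq).mean())
    else:
        raise InputError(f"unknown dem_mode {mode!r}")
    return z, dem_grid, factor
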