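"""Vegetation indices, pre/post differences and index screening.

Ten index variants are computed from the SuperDove-class bands: EVI, GEMI,
GNDVI1 (GREEN_I), GNDVI2 (GREEN), MSR, NDVI, SR, SAVI, WDRVI and YNDVI.
The difference direction is pre − post, so vegetation loss in a fire is
positive. Screening ranks indices by the masked mean difference inside a
burned-area delimitation, which is how the working pair (NDVI, YNDVI) is
selected for a sensor without a SWIR band.

Notes on two index definitions:

* MSR is implemented in its linear form, (NIR/RED − 1)/(NIR/RED + 1),
  which is algebraically identical to NDVI; the common literature variant
  divides by sqrt(NIR/RED) + 1 instead. The linear form is kept as the
  single behavior because it is the form this pipeline was designed around.
* GEMI uses the canonical published equations:
  n = (2(NIR² − RED²) + 1.5·NIR + 0.5·RED) / (NIR + RED + 0.5),
  GEMI = n(1 − 0.25n) − (RED − 0.125)/(1 − RED).

Pixels with a vanishing denominator become nodata rather than clamped
values — explicit over silent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_geodata import ConfigurationError, GridGeometry, InputError, Scene

__all__ = [
    "INDEX_NAMES",
    "IndexImage",
    "DifferenceImage",
    "compute_index",
    "index_difference",
    "masked_mean_difference",
    "screen_indices",
]

#: Denominators with magnitude below this are treated as zero -> nodata.
_DENOM_EPS = 1e-12


@dataclass
class IndexImage:
    """A single-band vegetation-index raster on the scene grid."""

    values: np.ndarray
    index_name: str
    grid: GridGeometry
    nodata_mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.values.shape != self.grid.shape or self.nodata_mask.shape != self.grid.shape:
            raise InputError("index planes must match the grid shape")


@dataclass
class DifferenceImage:
    """Pre-fire index minus post-fire index; nodata is the union of inputs."""

    values: np.ndarray
    index_name: str
    grid: GridGeometry
    nodata_mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.values.shape != self.grid.shape or self.nodata_mask.shape != self.grid.shape:
            raise InputError("difference planes must match the grid shape")


def _ratio(num: np.ndarray, den: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Elementwise num/den; returns (values, zero-denominator mask)."""
    bad = np.abs(den) < _DENOM_EPS
    with np.errstate(divide="ignore", invalid="ignore"):
        out = num / np.where(bad, np.nan, den)
    return out, bad


def _ndvi(s, p):
    return _ratio(s.band("NIR") - s.band("RED"), s.band("NIR") + s.band("RED"))


def _sr(s, p):
    return _ratio(s.band("NIR"), s.band("RED"))


def _savi(s, p):
    return _ratio(1.5 * (s.band("NIR") - s.band("RED")), s.band("NIR") + s.band("RED") + 0.5)


def _evi(s, p):
    nir, red, blue = s.band("NIR"), s.band("RED"), s.band("BLUE")
    return _ratio(2.5 * (nir - red), nir + 6.0 * red - 7.5 * blue + 1.0)


def _gemi(s, p):
    nir, red = s.band("NIR"), s.band("RED")
    n, bad1 = _ratio(2.0 * (nir**2 - red**2) + 1.5 * nir + 0.5 * red, nir + red + 0.5)
    tail, bad2 = _ratio(red - 0.125, 1.0 - red)
    return n * (1.0 - 0.25 * n) - tail, bad1 | bad2


def _msr(s, p):
    # linear form: with r = NIR/RED, (r-1)/(r+1) == NDVI where RED > 0
    r, bad1 = _ratio(s.band("NIR"), s.band("RED"))
    v, bad2 = _ratio(r - 1.0, r + 1.0)
    return v, bad1 | bad2


def _wdrvi(s, p):
    a = p.get("wdrvi_a", 0.1)
    if not (0.1 <= a <= 0.2):
        raise ConfigurationError("wdrvi_a must lie in [0.1, 0.2]")
    nir, red = s.band("NIR"), s.band("RED")
    return _ratio(a * nir - red, a * nir + red)


def _gndvi1(s, p):
    return _ratio(s.band("NIR") - s.band("GREEN_I"), s.band("NIR") + s.band("GREEN_I"))


def _gndvi2(s, p):
    return _ratio(s.band("NIR") - s.band("GREEN"), s.band("NIR") + s.band("GREEN"))


def _yndvi(s, p):
    return _ratio(s.band("NIR") - s.band("YELLOW"), s.band("NIR") + s.band("YELLOW"))


#: index name -> (required semantic bands, implementation)
_REGISTRY = {
    "EVI": (("NIR", "RED", "BLUE"), _evi),
    "GEMI": (("NIR", "RED"), _gemi),
    "GNDVI1": (("NIR", "GREEN_I"), _gndvi1),
    "GNDVI2": (("NIR", "GREEN"), _gndvi2),
    "MSR": (("NIR", "RED"), _msr),
    "NDVI": (("NIR", "RED"), _ndvi),
    "SR": (("NIR", "RED"), _sr),
    "SAVI": (("NIR", "RED"), _savi),
    "WDRVI": (("NIR", "RED"), _wdrvi),
    "YNDVI": (("NIR", "YELLOW"), _yndvi),
}

INDEX_NAMES = tuple(sorted(_REGISTRY))


def required_bands(index_name: str) -> tuple[str, ...]:
    """Semantic bands an index needs."""
    if index_name not in _REGISTRY:
        raise InputError(f"unknown index {index_name!r}; choose from {INDEX_NAMES}")
    return _REGISTRY[index_name][0]


def compute_index(scene: Scene, index_name: str, params: dict | None = None) -> IndexImage:
    """Evaluate one vegetation index per pixel on a scene.

    ``params`` currently carries ``wdrvi_a`` (WDRVI weighting, default 0.1).
    """
    if index_name not in _REGISTRY:
        raise InputError(f"unknown index {index_name!r}; choose from {INDEX_NAMES}")
    bands, fn = _REGISTRY[index_name]
    missing = [b for b in bands if b not in scene.band_map]
    if missing:
        raise ConfigurationError(
            f"index {index_name} requires bands {missing} absent from the band map"
        )
    values, zero_den = fn(scene, params or {})
    nodata = scene.nodata_mask | zero_den | ~np.isfinite(values)
    values = np.where(nodata, np.nan, values)
    return IndexImage(values=values, index_name=index_name, grid=scene.grid, nodata_mask=nodata)


def index_difference(pre: IndexImage, post: IndexImage) -> DifferenceImage:
    """Pre − post difference of the same index on the same grid."""
    if pre.index_name != post.index_name:
        raise InputError(
            f"index mismatch: {pre.index_name!r} vs {post.index_name!r}"
        )
    if pre.grid.shape != post.grid.shape:
        raise InputError("pre and post index images are on different grids")
    nodata = pre.nodata_mask | post.nodata_mask
    values = np.where(nodata, np.nan, pre.values - post.values)
    return DifferenceImage(
        values=values, index_name=pre.index_name, grid=pre.grid, nodata_mask=nodata
    )


def masked_mean_difference(diff: DifferenceImage, mask: np.ndarray) -> float:
    """Arithmetic mean of the difference over valid pixels where *mask* is true."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != diff.grid.shape:
        raise InputError("mask shape does not match the difference grid")
    effective = mask & ~diff.nodata_mask
    if not effective.any():
        raise InputError("mask selects no valid pixels")
    return float(diff.values[effective].mean())


def screen_indices(
    pre: Scene,
    post: Scene,
    mask: np.ndarray | None = None,
    params: dict | None = None,
) -> pd.DataFrame:
    """Masked mean pre−post difference for every computable index.

    Returns a DataFrame with columns ``index_name``, ``mean_difference``,
    ``n_pixels``, sorted by descending mean difference. Indices whose bands
    are missing from the band map are omitted with a warning. This is the
    screening step that motivates picking a high-contrast but
    radiometrically stable pair for the burned/unburned clustering.
    """
    if mask is None:
        mask = np.ones(pre.grid.shape, dtype=bool)
    rows = []
    for name in INDEX_NAMES:
        bands, _ = _REGISTRY[name]
        if not (pre.has_bands(bands) and post.has_bands(bands)):
            warnings.warn(
                f"index {name} skipped: required bands missing from the band map",
                stacklevel=2,
            )
            continue
        d = index_difference(
            compute_index(pre, name, params), compute_index(post, name, params)
        )
        effective = np.asarray(mask, bool) & ~d.nodata_mask
        rows.append(
            {
                "index_name": name,
                "mean_difference": float(d.values[effective].mean()) if effective.any() else np.nan,
                "n_pixels": int(effective.sum()),
            }
        )
    table = pd.DataFrame(rows, columns=["index_name", "mean_difference", "n_pixels"])
    return table.sort_values("mean_difference", ascending=False, ignore_index=True)
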