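"""Georeferenced raster and vector I/O and the common grid abstraction.

All rasters in a run share one :class:`GridGeometry` (the scene grid).
GeoTIFF files are read and written through :mod:`tifffile`, carrying the
standard GeoTIFF tags (ModelPixelScale, ModelTiepoint, GeoKeyDirectory)
and the GDAL nodata convention. Vector masks are GeoJSON polygons handled
with :mod:`shapely`.

Conventions: pixel (0, 0) is the upper-left pixel; the map coordinate of a
pixel is its center; rows increase southward. Pre/post scenes must already
share a grid — this module verifies grid equality rather than resampling,
so registration errors surface instead of being silently interpolated away.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import shapely
import tifffile
from shapely.geometry import shape as _shapely_shape

__all__ = [
    "BAND_NAMES",
    "GridGeometry",
    "Scene",
    "VectorMask",
    "ConfigurationError",
    "InputError",
    "read_scene",
    "read_raster",
    "write_raster",
    "load_vector_mask",
    "rasterize_mask",
    "grids_compatible",
]

#: Semantic band names of the 8-band SuperDove-class layout, in wavelength order.
BAND_NAMES = (
    "COASTAL_BLUE",
    "BLUE",
    "GREEN_I",
    "GREEN",
    "YELLOW",
    "RED",
    "RED_EDGE",
    "NIR",
)

#: Default band map for an 8-band SuperDove-style surface-reflectance product.
DEFAULT_BAND_MAP: dict[str, int] = {name: i for i, name in enumerate(BAND_NAMES)}

#: Nodata code used when writing categorical (integer) products.
CATEGORICAL_NODATA = 255

# GeoTIFF / GDAL tag ids
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GEO_KEY_DIRECTORY = 34735
_TAG_GDAL_NODATA = 42113

# GeoKey ids
_KEY_MODEL_TYPE = 1024
_KEY_RASTER_TYPE = 1025
_KEY_GEOGRAPHIC_CS = 2048
_KEY_PROJECTED_CS = 3072


class ConfigurationError(ValueError):
    """A run configuration item (band map, index choice, ...) is invalid."""


class InputError(ValueError):
    """An input file or array violates a precondition."""


@dataclass(frozen=True)
class GridGeometry:
    """Geometry of a north-up raster grid.

    ``origin_x``/``origin_y`` are the map coordinates of the outer corner of
    the upper-left pixel. ``crs_epsg`` identifies the coordinate reference
    system; it is carried through I/O but never used for reprojection.
    """

    n_rows: int
    n_cols: int
    pixel_size_x: float
    pixel_size_y: float
    origin_x: float
    origin_y: float
    crs_epsg: int | None = None

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise InputError("grid must have at least one row and one column")
        if self.pixel_size_x <= 0 or self.pixel_size_y <= 0:
            raise InputError("pixel sizes must be strictly positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def pixel_area_m2(self) -> float:
        return self.pixel_size_x * self.pixel_size_y

    def x_centers(self) -> np.ndarray:
        """Map x coordinate of each column's pixel centers."""
        return self.origin_x + (np.arange(self.n_cols) + 0.5) * self.pixel_size_x

    def y_centers(self) -> np.ndarray:
        """Map y coordinate of each row's pixel centers (decreasing)."""
        return self.origin_y - (np.arange(self.n_rows) + 0.5) * self.pixel_size_y

    def bounds(self) -> tuple[float, float, float, float]:
        """(min_x, min_y, max_x, max_y) of the grid extent."""
        return (
            self.origin_x,
            self.origin_y - self.n_rows * self.pixel_size_y,
            self.origin_x + self.n_cols * self.pixel_size_x,
            self.origin_y,
        )


def grids_compatible(a: GridGeometry, b: GridGeometry, tol_pixels: float = 1e-6) -> bool:
    """True if two grids share shape, pixel size and origin within *tol_pixels*."""
    if a.shape != b.shape:
        return False
    if not math.isclose(a.pixel_size_x, b.pixel_size_x, rel_tol=1e-9):
        return False
    if not math.isclose(a.pixel_size_y, b.pixel_size_y, rel_tol=1e-9):
        return False
    tol_x = tol_pixels * a.pixel_size_x
    tol_y = tol_pixels * a.pixel_size_y
    return abs(a.origin_x - b.origin_x) <= tol_x and abs(a.origin_y - b.origin_y) <= tol_y


@dataclass
class Scene:
    """A georeferenced multi-band surface-reflectance raster.

    ``bands`` has shape (n_bands, n_rows, n_cols); ``band_map`` maps semantic
    names (subset of :data:`BAND_NAMES`) to positions in the band axis.
    Reflectance is unitless, nominally in [0, 1] after scaling.
    """

    grid: GridGeometry
    bands: np.ndarray
    band_map: Mapping[str, int]
    nodata_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.bands = np.asarray(self.bands, dtype=np.float64)
        if self.bands.ndim != 3:
            raise InputError("bands must be a (n_bands, n_rows, n_cols) array")
        if self.bands.shape[1:] != self.grid.shape:
            raise InputError("band planes do not match the grid shape")
        n_bands = self.bands.shape[0]
        for name, pos in self.band_map.items():
            if name not in BAND_NAMES:
                raise ConfigurationError(f"unknown semantic band name {name!r}")
            if not (0 <= int(pos) < n_bands):
                raise ConfigurationError(
                    f"band map entry {name!r} -> {pos} outside the {n_bands} stored bands"
                )
        if self.nodata_mask is None:
            self.nodata_mask = ~np.isfinite(self.bands).all(axis=0)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != self.grid.shape:
                raise InputError("nodata_mask does not match the grid shape")

    def band(self, name: str) -> np.ndarray:
        """Return the reflectance plane for a semantic band name."""
        if name not in self.band_map:
            raise ConfigurationError(f"band {name!r} is not present in the band map")
        return self.bands[int(self.band_map[name])]

    def has_bands(self, names: Sequence[str]) -> bool:
        return all(n in self.band_map for n in names)


@dataclass
class VectorMask:
    """One or more polygons in the scene CRS (AOI or reference delimitation)."""

    polygons: list
    role: str = "aoi"  # {"aoi", "reference_delimitation"}

    def __post_init__(self) -> None:
        if not self.polygons:
            raise InputError("vector mask contains no polygons")
        fixed = []
        for geom in self.polygons:
            if geom.is_empty:
                raise InputError("vector mask contains an empty polygon")
            if not geom.is_valid:
                raise InputError("vector mask polygon is invalid (self-intersecting?)")
            fixed.append(geom)
        self.polygons = fixed

    @property
    def union(self):
        return shapely.union_all(self.polygons)


# ---------------------------------------------------------------------------
# GeoTIFF I/O


def _geokeys_for_epsg(epsg: int | None) -> tuple[int, ...]:
    """Encode a minimal GeoKeyDirectory for an EPSG code.

    Geographic CRSs (EPSG 4000–4999) go in GeographicTypeGeoKey, everything
    else in ProjectedCSTypeGeoKey. RasterType is PixelIsArea.
    """
    keys = [(_KEY_RASTER_TYPE, 0, 1, 1)]
    if epsg is not None:
        if 4000 <= epsg < 5000:
            keys.insert(0, (_KEY_MODEL_TYPE, 0, 1, 2))
            keys.append((_KEY_GEOGRAPHIC_CS, 0, 1, int(epsg)))
        else:
            keys.insert(0, (_KEY_MODEL_TYPE, 0, 1, 1))
            keys.append((_KEY_PROJECTED_CS, 0, 1, int(epsg)))
    keys.sort()
    flat: list[int] = [1, 1, 0, len(keys)]
    for k in keys:
        flat.extend(k)
    return tuple(flat)


def _epsg_from_geokeys(directory: Sequence[int] | None) -> int | None:
    if directory is None or len(directory) < 4:
        return None
    n_keys = int(directory[3])
    epsg = None
    for i in range(n_keys):
        key_id, location, _count, value = directory[4 + 4 * i : 8 + 4 * i]
        if location == 0 and key_id in (_KEY_PROJECTED_CS, _KEY_GEOGRAPHIC_CS):
            epsg = int(value)
    return epsg


def write_raster(
    data: np.ndarray,
    grid: GridGeometry,
    path: str | Path,
    *,
    nodata: float | int | None = None,
) -> None:
    """Write one plane (2-D) or a band stack (3-D, bands first) as GeoTIFF.

    Boolean planes are encoded as uint8 {0, 1} with nodata 255; other integer
    planes keep their dtype. The grid's geotransform and CRS are written as
    GeoTIFF tags so a round trip through :func:`read_raster` is lossless.
    """
    arr = np.asarray(data)
    if arr.ndim == 2:
        arr = arr[None, ...]
    if arr.ndim != 3:
        raise InputError("data must be 2-D or 3-D (bands first)")
    if arr.shape[1:] != grid.shape:
        raise InputError(
            f"data shape {arr.shape[1:]} does not match grid shape {grid.shape}"
        )
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
        if nodata is None:
            nodata = CATEGORICAL_NODATA

    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (grid.pixel_size_x, grid.pixel_size_y, 0.0), True),
        (
            _TAG_MODEL_TIEPOINT,
            "d",
            6,
            (0.0, 0.0, 0.0, grid.origin_x, grid.origin_y, 0.0),
            True,
        ),
    ]
    geokeys = _geokeys_for_epsg(grid.crs_epsg)
    extratags.append((_TAG_GEO_KEY_DIRECTORY, "H", len(geokeys), geokeys, True))
    if nodata is not None:
        txt = repr(float(nodata)) if isinstance(nodata, float) else str(int(nodata))
        extratags.append((_TAG_GDAL_NODATA, "s", len(txt) + 1, txt, True))

    squeeze = arr.shape[0] == 1
    out = arr[0] if squeeze else arr
    tifffile.imwrite(
        str(path),
        out,
        photometric="minisblack",
        planarconfig=None if squeeze else "separate",
        extratags=extratags,
    )


def read_raster(path: str | Path) -> tuple[np.ndarray, GridGeometry, float | None]:
    """Read a GeoTIFF; returns (bands-first array, grid, nodata value or None)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"raster file not found: {path}")
    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        scale_tag = page.tags.get(_TAG_MODEL_PIXEL_SCALE)
        tie_tag = page.tags.get(_TAG_MODEL_TIEPOINT)
        if scale_tag is None or tie_tag is None:
            raise InputError(f"{path} is not georeferenced (missing GeoTIFF tags)")
        psx, psy = float(scale_tag.value[0]), float(scale_tag.value[1])
        tie = tie_tag.value
        # tiepoint maps raster (i, j, k) -> model (x, y, z); anchor at (0, 0)
        origin_x = float(tie[3]) - float(tie[0]) * psx
        origin_y = float(tie[4]) + float(tie[1]) * psy
        geo_tag = page.tags.get(_TAG_GEO_KEY_DIRECTORY)
        epsg = _epsg_from_geokeys(geo_tag.value if geo_tag is not None else None)
        nodata_tag = page.tags.get(_TAG_GDAL_NODATA)
        nodata = None
        if nodata_tag is not None:
            try:
                nodata = float(str(nodata_tag.value).strip("\x00 "))
            except ValueError:
                nodata = None
        arr = tif.asarray()
    if arr.ndim == 2:
        arr = arr[None, ...]
    elif arr.ndim == 3 and arr.shape[0] not in (arr.shape[1], arr.shape[2]):
        pass  # already bands-first (planarconfig=separate)
    grid = GridGeometry(
        n_rows=arr.shape[1],
        n_cols=arr.shape[2],
        pixel_size_x=psx,
        pixel_size_y=psy,
        origin_x=origin_x,
        origin_y=origin_y,
        crs_epsg=epsg,
    )
    return arr, grid, nodata


def read_scene(
    path: str | Path,
    band_map: Mapping[str, int] | None = None,
    scale_factor: float = 1e-4,
    *,
    nodata: float | None = None,
) -> Scene:
    """Read a multispectral GeoTIFF into a :class:`Scene`.

    ``scale_factor`` converts stored digital numbers to reflectance
    (default 1e-4 for SuperDove-style integer storage; use 1.0 for rasters
    already in reflectance units). Pixels equal to the nodata value (from
    the file's GDAL tag or the *nodata* argument) in any band are flagged.
    """
    if scale_factor <= 0:
        raise ConfigurationError("scale_factor must be positive")
    if band_map is None:
        band_map = DEFAULT_BAND_MAP
    arr, grid, file_nodata = read_raster(path)
    if nodata is None:
        nodata = file_nodata
    n_bands = arr.shape[0]
    for name, pos in band_map.items():
        if not (0 <= int(pos) < n_bands):
            raise ConfigurationError(
                f"band map entry {name!r} -> {pos} not present in the {n_bands}-band file"
            )
    raw = arr.astype(np.float64)
    nodata_mask = ~np.isfinite(raw).all(axis=0)
    if nodata is not None:
        nodata_mask |= (raw == nodata).any(axis=0)
    reflectance = raw * scale_factor
    reflectance[:, nodata_mask] = np.nan
    return Scene(grid=grid, bands=reflectance, band_map=dict(band_map), nodata_mask=nodata_mask)


# ---------------------------------------------------------------------------
# Vector masks


def load_vector_mask(path: str | Path, role: str = "aoi") -> VectorMask:
    """Load polygons from a GeoJSON file (Feature, FeatureCollection or geometry)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"vector file not found: {path}")
    obj = json.loads(path.read_text())
    geoms = []

    def _collect(g: dict) -> None:
        t = g.get("type")
        if t == "FeatureCollection":
            for f in g.get("features", []):
                _collect(f)
        elif t == "Feature":
            _collect(g["geometry"])
        elif t in ("Polygon", "MultiPolygon"):
            geom = _shapely_shape(g)
            if geom.geom_type == "MultiPolygon":
                geoms.extend(geom.geoms)
            else:
                geoms.append(geom)
        elif t == "GeometryCollection":
            for sub in g.get("geometries", []):
                _collect(sub)
        else:
            raise InputError(f"unsupported GeoJSON geometry type {t!r}")

    _collect(obj)
    return VectorMask(polygons=geoms, role=role)


def rasterize_mask(mask: VectorMask, grid: GridGeometry) -> np.ndarray:
    """Rasterize polygons: a pixel is True iff its center lies inside any polygon."""
    geom = mask.union
    xs = grid.x_centers()
    ys = grid.y_centers()
    xx, yy = np.meshgrid(xs, ys)
    return shapely.contains_xy(geom, xx, yy)
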