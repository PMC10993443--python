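"""Georeferenced attribute grids and GeoTIFF I/O.

A :class:`RasterGrid` is a single-band grid of attribute values on a regular
latitude/longitude mesh (WGS84 geographic coordinates).  The registration
convention, stated explicitly because it matters for the point-to-cell link:

* ``origin_lat`` / ``origin_lon`` are the coordinates of the **upper-left
  corner** of the upper-left cell;
* latitude decreases with row index, longitude increases with column index;
* the center of cell ``(i, j)`` is
  ``(origin_lat - (i + 0.5) * resolution, origin_lon + (j + 0.5) * resolution)``.

The default resolution is 30 arc seconds (1/120 degree, roughly 1 km at the
equator), the grid spacing at which attribute maps are rasterized before
linking to survey points.

GeoTIFF files are written and read through :mod:`tifffile` using the standard
GeoTIFF tags (ModelPixelScale, ModelTiepoint, GeoKeyDirectory) plus the GDAL
nodata tag.  Only geographic WGS84 rasters are accepted on read; anything
else is rejected with an explicit message rather than silently reprojected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import tifffile

#: 30 arc seconds in decimal degrees.
ARCSEC30 = 1.0 / 120.0

_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GEO_KEY_DIRECTORY = 34735
_TAG_GDAL_NODATA = 42113

# GeoKeyDirectory for plain geographic WGS84 (PixelIsArea raster space).
_WGS84_GEOKEYS = (
    1, 1, 0, 3,
    1024, 0, 1, 2,      # GTModelTypeGeoKey = ModelTypeGeographic
    1025, 0, 1, 1,      # GTRasterTypeGeoKey = RasterPixelIsArea
    2048, 0, 1, 4326,   # GeographicTypeGeoKey = GCS_WGS_84
)


@dataclass
class RasterGrid:
    """Single-band georeferenced grid with explicit nodata handling."""

    values: np.ndarray
    origin_lat: float
    origin_lon: float
    resolution: float = ARCSEC30
    nodata: float = -9999.0
    attribute_name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("raster values must be a non-empty 2-D array")
        if not self.resolution > 0:
            raise ValueError("raster resolution must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds a valid value."""
        valid = self.values != self.nodata
        return valid & np.isfinite(self.values)

    def cell_center(self, i: int, j: int) -> tuple[float, float]:
        """(lat, lon) of the center of cell ``(i, j)``."""
        return (
            self.origin_lat - (i + 0.5) * self.resolution,
            self.origin_lon + (j + 0.5) * self.resolution,
        )

    def center_latitudes(self) -> np.ndarray:
        n = self.values.shape[0]
        return self.origin_lat - (np.arange(n) + 0.5) * self.resolution

    def center_longitudes(self) -> np.ndarray:
        m = self.values.shape[1]
        return self.origin_lon + (np.arange(m) + 0.5) * self.resolution

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(lat_min, lat_max, lon_min, lon_max) of the grid's outer edges."""
        n, m = self.values.shape
        return (
            self.origin_lat - n * self.resolution,
            self.origin_lat,
            self.origin_lon,
            self.origin_lon + m * self.resolution,
        )

    def cell_index(self, lat: float, lon: float) -> tuple[int, int]:
        """Row/column of the cell containing a point (no bounds check)."""
        i = int(np.floor((self.origin_lat - lat) / self.resolution))
        j = int(np.floor((lon - self.origin_lon) / self.resolution))
        return i, j

    def contains(self, lat: float, lon: float) -> bool:
        lat_min, lat_max, lon_min, lon_max = self.extent
        return lat_min <= lat <= lat_max and lon_min <= lon <= lon_max


def write_geotiff(grid: RasterGrid, path) -> str:
    """Write a :class:`RasterGrid` as a single-band WGS84 GeoTIFF."""
    res = grid.resolution
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (res, res, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6,
         (0.0, 0.0, 0.0, grid.origin_lon, grid.origin_lat, 0.0)),
        (_TAG_GEO_KEY_DIRECTORY, "H", len(_WGS84_GEOKEYS), _WGS84_GEOKEYS),
        (_TAG_GDAL_NODATA, "s", 0, repr(grid.nodata)),
    ]
    tifffile.imwrite(
        str(path),
        grid.values,
        extratags=extratags,
        description=grid.attribute_name,
    )
    return str(path)


def read_geotiff(path, attribute_name: str | None = None) -> RasterGrid:
    """Read a single-band GeoTIFF; rejects rasters that are not WGS84 geographic."""
    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        tags = page.tags
        _validate_wgs84(tags, path)
        if _TAG_MODEL_PIXEL_SCALE not in tags or _TAG_MODEL_TIEPOINT not in tags:
            raise ValueError(f"{path}: missing GeoTIFF georeferencing tags")
        sx, sy = tags[_TAG_MODEL_PIXEL_SCALE].value[:2]
        if not np.isclose(sx, sy):
            raise ValueError(f"{path}: anisotropic pixels are not supported")
        tp = tags[_TAG_MODEL_TIEPOINT].value
        if tuple(tp[:3]) != (0.0, 0.0, 0.0):
            raise ValueError(f"{path}: tiepoint must anchor the upper-left corner")
        origin_lon, origin_lat = tp[3], tp[4]
        nodata = -9999.0
        if _TAG_GDAL_NODATA in tags:
            nodata = float(tags[_TAG_GDAL_NODATA].value)
        values = page.asarray()
        name = attribute_name or (page.description or "")
    return RasterGrid(
        values=np.asarray(values, dtype=np.float64),
        origin_lat=float(origin_lat),
        origin_lon=float(origin_lon),
        resolution=float(sx),
        nodata=nodata,
        attribute_name=name,
    )


def _validate_wgs84(tags, path) -> None:
    if _TAG_GEO_KEY_DIRECTORY not in tags:
        raise ValueError(f"{path}: no GeoKeyDirectory; cannot verify the CRS is WGS84")
    keys = tags[_TAG_GEO_KEY_DIRECTORY].value
    entries = {keys[i]: keys[i + 3] for i in range(4, len(keys) - 3, 4)}
    if entries.get(1024) != 2:
        raise ValueError(
            f"{path}: raster is not in a geographic CRS "
            "(projected rasters must be converted to WGS84 before linking)"
        )
    if 2048 in entries and entries[2048] != 4326:
        raise ValueError(f"{path}: geographic CRS is not WGS84 (EPSG:4326)")
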