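"""Three-step geographic link between survey points and attribute grids.

Survey clusters carry GPS coordinates; biophysical attributes (drought index,
altitude, slope, soils, population density, crop cover) live on gridded maps.
A naive raster crossing keeps only one survey observation per grid cell, so
the link is done point-wise instead:

1. every attribute map is resampled (nearest neighbor) onto one common
   reference grid (:func:`resample_to_reference`);
2. each grid is exported to three flat vectors — cell-center latitude,
   cell-center longitude, attribute value — one entry per valid cell
   (:func:`grid_to_vectors`);
3. every survey point is matched to the vector entry whose cell center is
   nearest by great-circle distance (:func:`nearest_neighbor_link`); several
   points may share one cell.

Distances are haversine on a sphere of radius 6371.0088 km (the IUGG mean
Earth radius).  Ties are broken deterministically by the smallest cell
ordinal in row-major order.  :func:`harmonize` then drops records with any
missing analysis value, producing the full-matrix table all downstream
statistics operate on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .raster import RasterGrid

EARTH_RADIUS_KM = 6371.0088


@dataclass
class AttributeVectors:
    """Flat export of a grid's valid cells: (lat, lon, value) triplets.

    ``cell_index`` carries each entry's row-major flat index in the source
    grid so every linked value stays traceable to its source cell.
    """

    latitude: np.ndarray
    longitude: np.ndarray
    attribute: np.ndarray
    cell_index: np.ndarray = field(default=None)  # type: ignore[assignment]
    attribute_name: str = ""

    def __post_init__(self) -> None:
        self.latitude = np.asarray(self.latitude, dtype=np.float64)
        self.longitude = np.asarray(self.longitude, dtype=np.float64)
        self.attribute = np.asarray(self.attribute, dtype=np.float64)
        if not (len(self.latitude) == len(self.longitude) == len(self.attribute)):
            raise ValueError("latitude, longitude and attribute must have equal length")
        if self.cell_index is None:
            self.cell_index = np.arange(len(self.attribute))

    def __len__(self) -> int:
        return len(self.attribute)


@dataclass
class LinkedDataset:
    """Survey records augmented with linked attributes; no missing values."""

    records: pd.DataFrame
    dropped_count: int


def resample_to_reference(grid: RasterGrid, reference: RasterGrid) -> RasterGrid:
    """Nearest-neighbor resample of ``grid`` onto ``reference``'s mesh.

    Each output cell takes the value of the input cell containing the output
    cell's center; output cells whose centers fall outside the input extent
    become nodata.
    """
    g_lat_min, g_lat_max, g_lon_min, g_lon_max = grid.extent
    r_lat_min, r_lat_max, r_lon_min, r_lon_max = reference.extent
    if (g_lat_min >= r_lat_max or r_lat_min >= g_lat_max
            or g_lon_min >= r_lon_max or r_lon_min >= g_lon_max):
        raise ValueError(
            f"grids do not overlap: input extent {grid.extent}, "
            f"reference extent {reference.extent}"
        )
    lats = reference.center_latitudes()
    lons = reference.center_longitudes()
    rows = np.floor((grid.origin_lat - lats) / grid.resolution).astype(int)
    cols = np.floor((lons - grid.origin_lon) / grid.resolution).astype(int)
    n, m = grid.values.shape
    row_ok = (rows >= 0) & (rows < n)
    col_ok = (cols >= 0) & (cols < m)
    out = np.full(reference.values.shape, reference.nodata, dtype=np.float64)
    rr = np.clip(rows, 0, n - 1)[:, None]
    cc = np.clip(cols, 0, m - 1)[None, :]
    inside = row_ok[:, None] & col_ok[None, :]
    sampled = grid.values[rr, cc]
    # carry the input's own nodata through as the reference's nodata value
    sampled = np.where(sampled == grid.nodata, reference.nodata, sampled)
    out[inside] = sampled[inside]
    return RasterGrid(
        values=out,
        origin_lat=reference.origin_lat,
        origin_lon=reference.origin_lon,
        resolution=reference.resolution,
        nodata=reference.nodata,
        attribute_name=grid.attribute_name,
    )


def grid_to_vectors(grid: RasterGrid) -> AttributeVectors:
    """Export valid cells to (lat, lon, value) vectors in row-major order."""
    valid = grid.mask
    if not valid.any():
        warnings.warn(
            f"grid {grid.attribute_name!r} contains no valid cells; "
            "vectors are empty",
            stacklevel=2,
        )
    ii, jj = np.nonzero(valid)
    lat = grid.origin_lat - (ii + 0.5) * grid.resolution
    lon = grid.origin_lon + (jj + 0.5) * grid.resolution
    flat = ii * grid.values.shape[1] + jj
    return AttributeVectors(
        latitude=lat,
        longitude=lon,
        attribute=grid.values[ii, jj],
        cell_index=flat,
        attribute_name=grid.attribute_name,
    )


def vectors_to_grid(vectors: AttributeVectors, like: RasterGrid) -> RasterGrid:
    """Inverse of :func:`grid_to_vectors` on the mesh of ``like``."""
    out = np.full(like.values.shape, like.nodata, dtype=np.float64)
    ii, jj = np.divmod(vectors.cell_index, like.values.shape[1])
    out[ii, jj] = vectors.attribute
    return RasterGrid(
        values=out,
        origin_lat=like.origin_lat,
        origin_lon=like.origin_lon,
        resolution=like.resolution,
        nodata=like.nodata,
        attribute_name=vectors.attribute_name,
    )


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km between coordinate arrays (broadcasting)."""
    p1, l1, p2, l2 = (np.radians(np.asarray(a, dtype=np.float64))
                      for a in (lat1, lon1, lat2, lon2))
    dphi = p2 - p1
    dlam = l2 - l1
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def nearest_neighbor_link(
    points, vectors: AttributeVectors, chunk_size: int = 256
):
    """Link each (lat, lon) point to its nearest grid-cell center.

    Returns ``(values, distances_km, ordinals)`` where ``ordinals`` index into
    ``vectors``.  Ties are broken by the smallest ordinal (``argmin`` keeps
    the first minimum, and vector order is row-major cell order).  The scan
    is exhaustive, computed in chunks of points to bound memory.
    """
    if len(vectors) == 0:
        raise ValueError("cannot link against empty attribute vectors")
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim == 1:
        pts = pts[None, :]
    n = len(pts)
    values = np.empty(n)
    dists = np.empty(n)
    ordinals = np.empty(n, dtype=np.int64)
    for start in range(0, n, chunk_size):
        sl = slice(start, min(start + chunk_size, n))
        d = haversine_km(
            pts[sl, 0][:, None], pts[sl, 1][:, None],
            vectors.latitude[None, :], vectors.longitude[None, :],
        )
        best = np.argmin(d, axis=1)
        ordinals[sl] = best
        dists[sl] = d[np.arange(d.shape[0]), best]
        values[sl] = vectors.attribute[best]
    return values, dists, ordinals


def link_points(
    records: pd.DataFrame,
    rasters: dict[str, RasterGrid],
    lat_col: str = "lat",
    lon_col: str = "lon",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Attach one column per raster attribute to a point table.

    Returns the augmented table plus an audit log (one row per point per
    attribute: cell ordinal and link distance in km).
    """
    out = records.copy()
    pts = out[[lat_col, lon_col]].to_numpy(dtype=np.float64)
    audit_rows = []
    for name, grid in rasters.items():
        vectors = grid_to_vectors(grid)
        values, dists, ordinals = nearest_neighbor_link(pts, vectors)
        out[name] = values
        out[f"{name}_link_km"] = dists
        audit_rows.append(pd.DataFrame({
            "point": np.arange(len(out)),
            "attribute": name,
            "cell_ordinal": ordinals,
            "source_cell_index": vectors.cell_index[ordinals],
            "distance_km": dists,
        }))
    audit = pd.concat(audit_rows, ignore_index=True) if audit_rows else pd.DataFrame()
    return out, audit


def harmonize(
    records: pd.DataFrame, analysis_columns: list[str] | None = None
) -> LinkedDataset:
    """Drop rows with any missing analysis value → full-matrix dataset.

    Raises if nothing survives, with a per-column missingness diagnostic so
    the offending variable is identifiable.  Idempotent.
    """
    cols = list(analysis_columns) if analysis_columns is not None else list(records.columns)
    missing = records[cols].isna()
    keep = ~missing.any(axis=1)
    surviving = records.loc[keep].copy()
    dropped = int(len(records) - len(surviving))
    if len(records) > 0 and len(surviving) == 0:
        per_col = (100.0 * missing.mean()).round(1).to_dict()
        raise ValueError(
            "no records survive harmonization; per-column missingness (%): "
            f"{per_col}"
        )
    return LinkedDataset(records=surviving, dropped_count=dropped)
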