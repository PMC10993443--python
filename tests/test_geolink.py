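"""Raster I/O, resampling, vector export and the nearest-neighbor link."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from malnut.geolink import (
    AttributeVectors,
    grid_to_vectors,
    harmonize,
    haversine_km,
    link_points,
    nearest_neighbor_link,
    resample_to_reference,
    vectors_to_grid,
    EARTH_RADIUS_KM,
)
from malnut.raster import RasterGrid, read_geotiff, write_geotiff


def brute_force_link(points, vectors):
    """Independent per-point exhaustive haversine scan (the oracle)."""
    out = []
    for lat, lon in points:
        p1, l1 = np.radians(lat), np.radians(lon)
        p2 = np.radians(vectors.latitude)
        l2 = np.radians(vectors.longitude)
        a = (np.sin((p2 - p1) / 2) ** 2
             + np.cos(p1) * np.cos(p2) * np.sin((l2 - l1) / 2) ** 2)
        d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))
        best = 0
        for k in range(1, len(d)):
            if d[k] < d[best]:
                best = k
        out.append((vectors.attribute[best], d[best], best))
    return out


def grid4x4(values=None, nodata=-9999.0):
    v = np.arange(16, dtype=float).reshape(4, 4) if values is None else values
    return RasterGrid(values=v, origin_lat=10.0, origin_lon=125.0,
                      resolution=0.25, nodata=nodata)


class TestGeoTiff:
    def test_round_trip_bit_identical(self, tmp_path):
        grid = grid4x4()
        grid.attribute_name = "altitude"
        path = tmp_path / "g.tif"
        write_geotiff(grid, path)
        back = read_geotiff(path)
        assert np.array_equal(back.values, grid.values)
        assert back.origin_lat == grid.origin_lat
        assert back.origin_lon == grid.origin_lon
        assert back.resolution == grid.resolution
        assert back.nodata == grid.nodata
        assert back.attribute_name == "altitude"

    def test_non_wgs84_rejected(self, tmp_path):
        import tifffile
        path = tmp_path / "p.tif"
        # projected CRS (model type 1) must be refused
        keys = (1, 1, 0, 2, 1024, 0, 1, 1, 1025, 0, 1, 1)
        tifffile.imwrite(path, np.zeros((2, 2)), extratags=[
            (33550, "d", 3, (0.1, 0.1, 0.0)),
            (33922, "d", 6, (0, 0, 0, 125.0, 10.0, 0.0)),
            (34735, "H", len(keys), keys),
        ])
        with pytest.raises(ValueError, match="geographic"):
            read_geotiff(path)

    def test_missing_georeference_rejected(self, tmp_path):
        import tifffile
        path = tmp_path / "bare.tif"
        tifffile.imwrite(path, np.zeros((2, 2)))
        with pytest.raises(ValueError):
            read_geotiff(path)


class TestResample:
    def test_identity(self):
        g = grid4x4()
        out = resample_to_reference(g, g)
        assert np.array_equal(out.values, g.values)

    def test_constant_grid_stays_constant(self):
        g = grid4x4(np.full((4, 4), 7.0))
        ref = RasterGrid(values=np.zeros((5, 5)), origin_lat=9.9,
                         origin_lon=125.05, resolution=0.15)
        out = resample_to_reference(g, ref)
        valid = out.values != ref.nodata
        assert valid.any()
        assert np.all(out.values[valid] == 7.0)

    def test_checkerboard_block_replication(self):
        """Half-resolution resampling replicates each source cell 2×2
        (cell centers enumerated by hand via the kron oracle)."""
        src = RasterGrid(values=np.array([[1.0, 2.0], [3.0, 4.0]]),
                         origin_lat=10.0, origin_lon=125.0, resolution=1.0)
        ref = RasterGrid(values=np.zeros((4, 4)), origin_lat=10.0,
                         origin_lon=125.0, resolution=0.5)
        out = resample_to_reference(src, ref)
        expected = np.kron(src.values, np.ones((2, 2)))
        assert np.array_equal(out.values, expected)

    def test_disjoint_extents_rejected(self):
        a = grid4x4()
        b = RasterGrid(values=np.zeros((4, 4)), origin_lat=50.0,
                       origin_lon=0.0, resolution=0.25)
        with pytest.raises(ValueError, match="overlap"):
            resample_to_reference(a, b)

    def test_outside_input_becomes_nodata(self):
        src = RasterGrid(values=np.ones((2, 2)), origin_lat=10.0,
                         origin_lon=125.0, resolution=0.25)
        ref = RasterGrid(values=np.zeros((4, 4)), origin_lat=10.25,
                         origin_lon=124.75, resolution=0.25)
        out = resample_to_reference(src, ref)
        assert out.values[0, 0] == ref.nodata      # above/left of input
        assert out.values[1, 1] == 1.0


class TestGridToVectors:
    def test_nodata_cells_excluded(self):
        v = np.array([[1.0, -9999.0], [3.0, 4.0]])
        vec = grid_to_vectors(RasterGrid(values=v, origin_lat=10.0,
                                         origin_lon=125.0, resolution=0.25))
        assert len(vec) == 3

    def test_cell_center_formula(self):
        g = RasterGrid(values=np.ones((2, 2)), origin_lat=10.0,
                       origin_lon=125.0, resolution=0.25)
        vec = grid_to_vectors(g)
        assert vec.latitude[0] == pytest.approx(9.875)
        assert vec.longitude[0] == pytest.approx(125.125)

    def test_round_trip_rebuilds_grid(self):
        v = np.arange(16, dtype=float).reshape(4, 4)
        v[2, 1] = -9999.0
        g = grid4x4(v)
        back = vectors_to_grid(grid_to_vectors(g), g)
        assert np.array_equal(back.values, g.values)

    def test_all_nodata_warns_and_empty(self):
        g = grid4x4(np.full((4, 4), -9999.0))
        with pytest.warns(UserWarning, match="no valid cells"):
            vec = grid_to_vectors(g)
        assert len(vec) == 0


class TestNearestNeighborLink:
    def test_point_at_cell_center_distance_zero(self):
        vec = grid_to_vectors(grid4x4())
        vals, dists, ords = nearest_neighbor_link([(9.875, 125.125)], vec)
        assert ords[0] == 0
        assert dists[0] == pytest.approx(0.0, abs=1e-9)
        assert vals[0] == 0.0

    def test_single_entry_vectors(self):
        vec = AttributeVectors(latitude=[0.0], longitude=[0.0], attribute=[42.0])
        vals, _, ords = nearest_neighbor_link([(10, 10), (-5, 3)], vec)
        assert np.all(vals == 42.0)
        assert np.all(ords == 0)

    def test_empty_vectors_rejected(self):
        vec = AttributeVectors(latitude=[], longitude=[], attribute=[])
        with pytest.raises(ValueError, match="empty"):
            nearest_neighbor_link([(0.0, 0.0)], vec)

    def test_matches_brute_force_oracle(self, rng):
        cells = rng.uniform([-9.5, 124.0], [-8.1, 127.3], size=(400, 2))
        vec = AttributeVectors(latitude=cells[:, 0], longitude=cells[:, 1],
                               attribute=rng.normal(size=400))
        pts = rng.uniform([-9.5, 124.0], [-8.1, 127.3], size=(100, 2))
        vals, dists, ords = nearest_neighbor_link(pts, vec, chunk_size=17)
        for k, (v, d, o) in enumerate(brute_force_link(pts, vec)):
            assert ords[k] == o
            assert dists[k] == pytest.approx(d, rel=1e-12)
            assert vals[k] == v

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_oracle_equivalence_property(self, seed):
        r = np.random.default_rng(seed)
        n_pts = int(r.integers(1, 12))
        n_cells = int(r.integers(1, 40))
        vec = AttributeVectors(
            latitude=r.uniform(-60, 60, n_cells),
            longitude=r.uniform(-179, 179, n_cells),
            attribute=r.normal(size=n_cells),
        )
        pts = np.column_stack([r.uniform(-60, 60, n_pts),
                               r.uniform(-179, 179, n_pts)])
        _, _, ords = nearest_neighbor_link(pts, vec)
        expected = [o for _, _, o in brute_force_link(pts, vec)]
        assert list(ords) == expected

    def test_point_inside_cell_links_to_that_cell(self):
        g = grid4x4()
        vec = grid_to_vectors(g)
        # a point near the center of cell (1, 2): nearer it than any other
        lat, lon = g.cell_center(1, 2)
        vals, _, _ = nearest_neighbor_link([(lat + 0.01, lon - 0.01)], vec)
        assert vals[0] == g.values[1, 2]


class TestHarmonize:
    def make_df(self):
        return pd.DataFrame({
            "a": [1.0, np.nan, 3.0, 4.0],
            "b": [1.0, 2.0, np.nan, 4.0],
        })

    def test_no_missing_no_drop(self):
        df = pd.DataFrame({"a": [1.0, 2.0]})
        out = harmonize(df)
        assert out.dropped_count == 0
        assert len(out.records) == 2

    def test_counts(self):
        out = harmonize(self.make_df())
        assert out.dropped_count == 2
        assert len(out.records) == 2

    def test_idempotent(self):
        once = harmonize(self.make_df())
        twice = harmonize(once.records)
        assert twice.dropped_count == 0
        pd.testing.assert_frame_equal(twice.records, once.records)

    def test_dropping_allmissing_column_never_reduces_survivors(self):
        df = self.make_df()
        df["c"] = np.nan
        with pytest.raises(ValueError, match="missingness"):
            harmonize(df)                       # 'c' kills every row
        out = harmonize(df, ["a", "b"])         # excluding it restores rows
        assert len(out.records) == 2

    def test_paper_scale_counts(self, rng):
        """9806 rows of which 2428 lack Z-scores leave 7378 survivors."""
        n = 9806
        df = pd.DataFrame({"haz": rng.normal(size=n)})
        missing_idx = rng.choice(n, size=2428, replace=False)
        df.loc[missing_idx, "haz"] = np.nan
        out = harmonize(df, ["haz"])
        assert len(out.records) == 7378
        assert out.dropped_count == 2428


def test_link_points_adds_attribute_and_distance(small_bundle):
    records = small_bundle.records.head(40)
    linked, audit = link_points(records, {"mvhi": small_bundle.rasters["mvhi"]})
    assert "mvhi" in linked.columns and "mvhi_link_km" in linked.columns
    assert (linked["mvhi_link_km"] >= 0).all()
    assert len(audit) == 40
    # every linked value is traceable to a real cell of the source grid
    grid = small_bundle.rasters["mvhi"]
    flat = grid.values.ravel()
    assert np.all(flat[audit["source_cell_index"]] == linked["mvhi"].to_numpy())


def test_haversine_known_distance():
    # one degree of longitude at the equator
    d = haversine_km(0.0, 0.0, 0.0, 1.0)
    assert d == pytest.approx(2 * np.pi * EARTH_RADIUS_KM / 360, rel=1e-9)
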