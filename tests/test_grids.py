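"""Raster I/O, point extraction geometry and sample-table handling."""

import numpy as np
import pandas as pd
import pytest

from plumascape import (
    GeoGrid,
    GridError,
    GridStack,
    descriptive_stats,
    extract_at_points,
    read_geotiff,
    read_samples_csv,
    validate_samples,
    write_geotiff,
)


class TestGeoTiffRoundTrip:
    def test_constant_grid_identity(self, tmp_path):
        g = GeoGrid(np.full((3, 3), 7.0), -10.0, 5.0, 1.0, 1.0)
        write_geotiff(g, tmp_path / "g.tif")
        g2 = read_geotiff(tmp_path / "g.tif")
        np.testing.assert_array_equal(g2.values, g.values)

    def test_nodata_preserved(self, tmp_path):
        vals = np.full((3, 3), 1.5)
        vals[1, 2] = np.nan
        g = GeoGrid(vals, 0.0, 3.0, 1.0, 1.0, nodata=-9999.0)
        write_geotiff(g, tmp_path / "g.tif")
        g2 = read_geotiff(tmp_path / "g.tif")
        assert np.isnan(g2.values[1, 2])
        assert np.isfinite(g2.values[0, 0])
        assert g2.nodata == -9999.0

    def test_transform_round_trip(self, tmp_path):
        g = GeoGrid(np.zeros((2, 2)), -60.0, 0.0, 0.5, 0.5)
        write_geotiff(g, tmp_path / "g.tif")
        g2 = read_geotiff(tmp_path / "g.tif")
        assert g2.origin_x == -60.0
        assert g2.origin_y == 0.0
        assert g2.cell_size_x == 0.5
        assert g2.cell_size_y == 0.5
        assert g2.crs_id == "EPSG:4326"

    def test_random_grids_with_nodata_patterns(self, tmp_path, rng):
        for i in range(5):
            vals = rng.normal(size=(6, 4)).astype(np.float32).astype(float)
            mask = rng.random((6, 4)) < 0.25
            vals[mask] = np.nan
            g = GeoGrid(vals, rng.uniform(-100, 0), rng.uniform(0, 50), 0.25, 0.5)
            write_geotiff(g, tmp_path / f"r{i}.tif")
            g2 = read_geotiff(tmp_path / f"r{i}.tif")
            np.testing.assert_array_equal(np.isnan(g2.values), np.isnan(vals))
            np.testing.assert_allclose(
                g2.values[~mask], vals[~mask], rtol=1e-6
            )

    def test_unreadable_file_names_path(self, tmp_path):
        p = tmp_path / "bad.tif"
        p.write_text("not a tiff")
        with pytest.raises(GridError, match="bad.tif"):
            read_geotiff(p)

    def test_missing_file_names_path(self, tmp_path):
        with pytest.raises(GridError, match="nothere.tif"):
            read_geotiff(tmp_path / "nothere.tif")


class TestExtraction:
    def test_constant_grid_any_point(self, make_samples_fn):
        g = GeoGrid(np.full((4, 4), 42.0), 0.0, 4.0, 1.0, 1.0)
        samples = make_samples_fn([0.3, 3.9, 2.0], [0.1, 3.9, 2.0], [0, 0, 0])
        m = extract_at_points(GridStack({"c": g}), samples)
        assert (m.data["c"] == 42.0).all()

    def test_hand_geometry(self, small_grid, make_samples_fn):
        # point (1.5, 0.5) lies in column 1, row 1 -> value 4
        samples = make_samples_fn([1.5], [0.5], [-50.0])
        m = extract_at_points(GridStack({"g": small_grid}), samples)
        assert m.data["g"].iloc[0] == 4.0

    def test_out_of_extent_flagged(self, small_grid, make_samples_fn):
        samples = make_samples_fn([99.0, 0.5], [89.0, 1.5], [0.0, 0.0])
        m = extract_at_points(GridStack({"g": small_grid}), samples)
        assert m.out_of_extent == ["S0"]
        assert list(m.data.index) == ["S1"]

    def test_nodata_rows_dropped_and_listed(self, make_samples_fn):
        vals = np.array([[1.0, np.nan], [3.0, 4.0]])
        g = GeoGrid(vals, 0.0, 2.0, 1.0, 1.0)
        samples = make_samples_fn([1.5, 0.5], [1.5, 0.5], [0.0, 0.0])
        m = extract_at_points(GridStack({"g": g}), samples)
        assert m.dropped_nodata == ["S0"]
        assert list(m.data.index) == ["S1"]

    def test_cell_center_enumeration(self, rng):
        """Extraction at the exact center of cell (i, j) returns values[i, j]."""
        g = GeoGrid(rng.normal(size=(5, 7)), -20.0, 10.0, 0.5, 0.25)
        lon, lat = np.meshgrid(g.x_centers, g.y_centers)
        table = pd.DataFrame(
            {
                "sample_id": [f"P{i}" for i in range(lon.size)],
                "lon": lon.ravel(),
                "lat": lat.ravel(),
                "d2h_f": np.zeros(lon.size),
            }
        )
        m = extract_at_points(GridStack({"g": g}), table)
        np.testing.assert_array_equal(
            m.data["g"].to_numpy().reshape(g.values.shape), g.values
        )


class TestSampleTable:
    def test_descriptive_stats_single_row(self, make_samples_fn):
        s = descriptive_stats(make_samples_fn([-50.0], [-10.0], [-50.0]))
        assert s["n_samples"] == 1
        assert s["d2h_min"] == s["d2h_max"] == s["d2h_mean"] == -50.0

    def test_descriptive_stats_permutation_invariant(self, rng, make_samples_fn):
        n = 40
        t = make_samples_fn(
            rng.uniform(-70, -40, n), rng.uniform(-30, 5, n), rng.normal(-60, 20, n),
            species=[f"sp{i % 7}" for i in range(n)],
        )
        shuffled = t.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a, b = descriptive_stats(t), descriptive_stats(shuffled)
        assert a.keys() == b.keys()
        for k in a:  # float summation order may differ at machine precision
            assert a[k] == pytest.approx(b[k], rel=1e-12)

    def test_unique_locations_counts_pairs(self, make_samples_fn):
        t = make_samples_fn([-50, -50, -60], [0, 0, 1], [0, 1, 2])
        assert descriptive_stats(t)["n_unique_locations"] == 2

    def test_missing_column_named(self, tmp_path):
        pd.DataFrame({"sample_id": ["a"], "lon": [0.0], "lat": [0.0]}).to_csv(
            tmp_path / "s.csv", index=False
        )
        with pytest.raises(GridError, match="d2h_f"):
            read_samples_csv(tmp_path / "s.csv")

    def test_non_numeric_d2h_names_row(self, make_samples_fn):
        t = make_samples_fn([0.0, 1.0], [0.0, 1.0], [1.0, 2.0])
        t.loc[1, "d2h_f"] = "oops"
        with pytest.raises(GridError, match="S1"):
            validate_samples(t)

    def test_duplicate_ids_rejected(self, make_samples_fn):
        t = make_samples_fn([0.0, 1.0], [0.0, 1.0], [1.0, 2.0])
        t["sample_id"] = ["A", "A"]
        with pytest.raises(GridError, match="A"):
            validate_samples(t)


class TestStack:
    def test_misaligned_layer_rejected(self):
        a = GeoGrid(np.zeros((2, 2)), 0.0, 2.0, 1.0, 1.0)
        b = GeoGrid(np.zeros((3, 3)), 0.0, 2.0, 1.0, 1.0)
        stack = GridStack({"a": a})
        with pytest.raises(GridError, match="aligned"):
            stack.add("b", b)

    def test_duplicate_name_rejected(self):
        a = GeoGrid(np.zeros((2, 2)), 0.0, 2.0, 1.0, 1.0)
        stack = GridStack({"a": a})
        with pytest.raises(GridError, match="duplicate"):
            stack.add("a", a)
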