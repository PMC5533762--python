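import math

import numpy as np
import pandas as pd
import pytest

from canopylidar.point_cloud import (
    ContractError,
    PointCloud,
    PointTableFormatError,
    build_dem,
    clip_circular,
    normalize_heights,
    point_density,
    read_point_table,
    write_point_table,
)

from conftest import make_cloud


class TestReadPointTable:
    def test_parses_tiny_fixture(self, tiny_table):
        cloud = read_point_table(tiny_table)
        assert len(cloud) == 3
        assert cloud.n_pulses() == 2
        assert cloud.height_mode == "elevation"

    def test_round_trip_preserves_points(self, tiny_table, tmp_path):
        cloud = read_point_table(tiny_table)
        out = tmp_path / "out.csv"
        write_point_table(cloud, out)
        again = read_point_table(out)
        pd.testing.assert_frame_equal(
            cloud.data.sort_values(["x", "z"]).reset_index(drop=True),
            again.data.sort_values(["x", "z"]).reset_index(drop=True),
        )

    def test_return_number_exceeding_total_is_format_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "x,y,z,return_number,number_of_returns,pulse_id,point_class\n"
            "1,1,10,3,2,p1,vegetation\n"
        )
        with pytest.raises(PointTableFormatError):
            read_point_table(path)

    def test_missing_column_is_format_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("x,y,z\n1,2,3\n")
        with pytest.raises(PointTableFormatError, match="missing"):
            read_point_table(path)

    def test_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "x,y,z,return_number,number_of_returns,pulse_id,point_class\n"
            "1,1,10,1,1,p1,vegetation\n"
            "1,oops,10,1,1,p2,vegetation\n"
        )
        with pytest.raises(PointTableFormatError, match="line 3"):
            read_point_table(path)

    def test_las_round_trip(self, tiny_table, tmp_path):
        laspy = pytest.importorskip("laspy")  # optional dependency
        cloud = read_point_table(tiny_table)
        las_path = tmp_path / "out.las"
        write_point_table(cloud, las_path)
        again = read_point_table(las_path)
        assert len(again) == len(cloud)
        # coordinates preserved within the 1 mm storage scale
        np.testing.assert_allclose(
            np.sort(again.data["z"].to_numpy()), np.sort(cloud.data["z"].to_numpy()),
            atol=1e-3,
        )
        assert again.n_pulses() == cloud.n_pulses()

    def test_inconsistent_pulse_metadata_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "x,y,z,return_number,number_of_returns,pulse_id,point_class\n"
            "1,1,10,1,2,p1,vegetation\n"
            "1,1,8,2,3,p1,vegetation\n"
        )
        with pytest.raises(PointTableFormatError, match="inconsistent"):
            read_point_table(path)


class TestBuildDem:
    def test_constant_ground(self, flat_ground_cloud):
        dem = build_dem(flat_ground_cloud)
        assert np.allclose(dem.values, 100.0)

    def test_planar_ground_matches_analytic_plane(self):
        # z = 0.1 * x sampled densely: cell means within 0.1*cell of the plane
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 20, 4000)
        y = rng.uniform(0, 20, 4000)
        cloud = make_cloud(x, y, 0.1 * x, point_class="ground", height_mode="elevation")
        dem = build_dem(cloud, cell_size=1.0)
        ny, nx = dem.values.shape
        cx = dem.origin[0] + (np.arange(nx) + 0.5) * dem.cell_size
        expected = 0.1 * cx  # plane is independent of y
        assert np.abs(dem.values - expected[None, :]).max() <= 0.1 * dem.cell_size

    def test_void_cell_filled_from_neighbour(self):
        # 3x3 layout with the centre cell empty
        xs, ys, zs = [], [], []
        for i in range(3):
            for j in range(3):
                if (i, j) == (1, 1):
                    continue
                xs.append(i + 0.5)
                ys.append(j + 0.5)
                zs.append(50.0)
        cloud = make_cloud(xs, ys, zs, point_class="ground", height_mode="elevation")
        dem = build_dem(cloud, cell_size=1.0)
        assert dem.values[1, 1] == 50.0

    def test_too_few_ground_points(self):
        cloud = make_cloud([0, 1], [0, 1], [9, 9], point_class="ground", height_mode="elevation")
        with pytest.raises(ContractError):
            build_dem(cloud)


class TestNormalizeHeights:
    def _dem(self, flat_ground_cloud):
        return build_dem(flat_ground_cloud)

    def test_subtracts_dem(self, flat_ground_cloud):
        dem = self._dem(flat_ground_cloud)
        cloud = make_cloud([5.0], [5.0], [105.0], height_mode="elevation")
        out = normalize_heights(cloud, dem)
        assert out.z[0] == pytest.approx(5.0)
        assert out.height_mode == "above_ground"

    def test_ground_points_removed(self, flat_ground_cloud):
        dem = self._dem(flat_ground_cloud)
        cloud = make_cloud(
            [5.0, 6.0], [5.0, 6.0], [105.0, 100.0],
            point_class=["vegetation", "ground"], height_mode="elevation",
        )
        out = normalize_heights(cloud, dem)
        assert len(out) == 1
        assert (out.data["point_class"] == "vegetation").all()

    def test_negative_heights_clamped(self, flat_ground_cloud):
        dem = self._dem(flat_ground_cloud)
        cloud = make_cloud([5.0], [5.0], [99.5], height_mode="elevation")
        out = normalize_heights(cloud, dem)
        assert out.z[0] == 0.0

    def test_count_identity(self, flat_ground_cloud):
        dem = self._dem(flat_ground_cloud)
        cloud = make_cloud(
            [1, 2, 3, 4], [1, 2, 3, 4], [105, 101, 100, 108],
            point_class=["vegetation", "vegetation", "ground", "vegetation"],
            height_mode="elevation",
        )
        out = normalize_heights(cloud, dem)
        assert len(out) == len(cloud) - int(cloud.is_ground.sum())

    def test_requires_elevation_mode(self, flat_ground_cloud):
        dem = self._dem(flat_ground_cloud)
        cloud = make_cloud([1.0], [1.0], [5.0], height_mode="above_ground")
        with pytest.raises(ContractError):
            normalize_heights(cloud, dem)


class TestClipCircular:
    def test_inside_plot_not_in_buffer(self):
        cloud = make_cloud([14.9], [0.0], [10.0])
        out = clip_circular(cloud, (0, 0), 15.0)
        assert len(out) == 1
        assert not out.data["in_buffer"].iloc[0]

    def test_buffer_point_retained_and_tagged(self):
        cloud = make_cloud([16.0], [0.0], [10.0])
        out = clip_circular(cloud, (0, 0), 15.0, buffer=4.7)
        assert len(out) == 1
        assert out.data["in_buffer"].iloc[0]

    def test_beyond_buffer_dropped(self):
        cloud = make_cloud([20.0], [0.0], [10.0])
        out = clip_circular(cloud, (0, 0), 15.0, buffer=4.7)
        assert len(out) == 0

    def test_area_is_core_plot(self):
        cloud = make_cloud([0.0], [0.0], [10.0])
        out = clip_circular(cloud, (0, 0), 15.0, buffer=4.7)
        assert out.area == pytest.approx(math.pi * 225.0)

    def test_buffered_clip_is_superset(self):
        rng = np.random.default_rng(0)
        cloud = make_cloud(rng.uniform(-25, 25, 500), rng.uniform(-25, 25, 500), np.ones(500))
        plain = clip_circular(cloud, (0, 0), 15.0)
        buffered = clip_circular(cloud, (0, 0), 15.0, buffer=4.7)
        plain_set = set(map(tuple, plain.data[["x", "y"]].to_numpy()))
        buf_set = set(map(tuple, buffered.data[["x", "y"]].to_numpy()))
        assert plain_set <= buf_set


class TestPointDensity:
    def test_simple_ratio(self):
        cloud = make_cloud(np.zeros(400), np.zeros(400), np.zeros(400), area=100.0)
        assert point_density(cloud) == pytest.approx(4.0)

    def test_empty_cloud(self):
        cloud = make_cloud([], [], [], area=50.0)
        assert point_density(cloud) == 0.0

    def test_unset_area_is_contract_error(self):
        cloud = make_cloud([0.0], [0.0], [0.0])
        with pytest.raises(ContractError):
            point_density(cloud)

    def test_generator_self_consistency(self):
        # a treeless scan at nominal 50 pulses/m^2 yields ~50 ground pt/m^2
        from canopylidar.synthetic import ScanConfig, Stand, simulate_scan

        stand = Stand(trees=[], plot_radius=10.0, crown_shape="paraboloid", terrain="flat")
        cloud = simulate_scan(stand, ScanConfig(pulse_density=50.0, seed=3))
        assert point_density(cloud) == pytest.approx(50.0, rel=0.10)
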