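import numpy as np
import pytest

from vinecwsi.errors import ContractError, MissingMetadataError
from vinecwsi.geodata import (
    AttributedPointCloud,
    GridTransform,
    RasterGrid,
    RoiPolygon,
    read_cloud,
    read_raster,
    write_cloud,
    write_raster,
)


class TestGridTransform:
    def test_positive_cell_sizes_required(self):
        with pytest.raises(ContractError):
            GridTransform(0, 0, -1.0, 1.0)
        with pytest.raises(ContractError):
            GridTransform(0, 0, 1.0, 0.0)

    def test_half_open_cell_rule(self):
        t = GridTransform(x0=0.0, y0=4.0, dx=1.0, dy=1.0)
        # left/top edges inclusive, right/bottom exclusive
        assert t.index_of(0.0, 4.0) == (0, 0)
        assert t.index_of(1.0, 4.0) == (0, 1)
        assert t.index_of(0.0, 3.0) == (1, 0)
        assert t.index_of(0.5, 3.5) == (0, 0)

    def test_every_point_maps_to_exactly_one_cell(self):
        t = GridTransform(x0=0.0, y0=10.0, dx=0.5, dy=0.5)
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 10, 500)
        y = rng.uniform(0, 10, 500)
        r1, c1 = t.index_of(x, y)
        r2, c2 = t.index_of(x, y)
        assert np.array_equal(r1, r2) and np.array_equal(c1, c2)

    def test_center_roundtrip(self):
        t = GridTransform(x0=5.0, y0=20.0, dx=0.25, dy=0.5)
        x, y = t.cell_center(3, 7)
        assert t.index_of(x, y) == (3, 7)


class TestRasterRoundtrip:
    def test_write_read_identity(self, tmp_path, raster_factory):
        grid = raster_factory([[1.0, 2.0], [3.0, 4.0]])
        path = tmp_path / "r.tif"
        write_raster(grid, path)
        back = read_raster(path)
        np.testing.assert_array_equal(back.values, grid.values)
        assert back.transform.almost_equals(grid.transform)
        assert back.crs_label == grid.crs_label

    def test_float_values_bit_identical(self, tmp_path, raster_factory):
        vals = np.array([[1.5, -2.25], [0.125, 1e6]], dtype=np.float32)
        grid = raster_factory(vals)
        write_raster(grid, tmp_path / "r.tif")
        back = read_raster(tmp_path / "r.tif")
        assert np.array_equal(back.values.astype(np.float32), vals)

    def test_nodata_tag_semantics(self, tmp_path, raster_factory):
        grid = raster_factory([[255.0, 1.0], [2.0, 255.0]], nodata=255.0)
        write_raster(grid, tmp_path / "r.tif")
        back = read_raster(tmp_path / "r.tif")
        assert back.nodata == 255.0
        np.testing.assert_array_equal(back.valid_mask, [[False, True], [True, False]])

    def test_all_nodata_grid(self, tmp_path, raster_factory):
        grid = raster_factory(np.full((3, 3), np.nan))
        write_raster(grid, tmp_path / "r.tif")
        back = read_raster(tmp_path / "r.tif")
        assert not back.valid_mask.any()
        assert back.valid_values().size == 0

    def test_missing_file(self):
        with pytest.raises(FileNotFoundError):
            read_raster("/nonexistent/never.tif")

    def test_missing_georeferencing_is_explicit(self, tmp_path):
        import tifffile

        path = tmp_path / "plain.tif"
        tifffile.imwrite(path, np.zeros((2, 2), dtype=np.float32))
        with pytest.raises(MissingMetadataError, match="georeferencing"):
            read_raster(path)

    def test_values_outside_unit_interval_not_clipped(self, tmp_path, raster_factory):
        grid = raster_factory([[-0.1, 1.3], [0.5, 2.0]])
        write_raster(grid, tmp_path / "c.tif")
        back = read_raster(tmp_path / "c.tif")
        assert back.values.min() == pytest.approx(-0.1)
        assert back.values.max() == pytest.approx(2.0)


class TestCloudModel:
    def test_attribute_length_checked(self):
        with pytest.raises(ContractError):
            AttributedPointCloud(coords=np.zeros((3, 3)), temperature=[1.0],
                                 temperature_unit="celsius")

    def test_temperature_needs_declared_unit(self):
        with pytest.raises(ContractError, match="unit"):
            AttributedPointCloud(coords=np.zeros((2, 3)), temperature=[1.0, 2.0])

    def test_non_finite_coords_rejected(self):
        with pytest.raises(ContractError):
            AttributedPointCloud(coords=[[0, 0, np.nan]])

    def test_subset_preserves_order(self):
        cloud = AttributedPointCloud(coords=np.arange(15).reshape(5, 3).astype(float),
                                     scalars={"s": np.arange(5.0)})
        sub = cloud.subset(np.array([True, False, True, True, False]))
        np.testing.assert_array_equal(sub.scalars["s"], [0.0, 2.0, 3.0])


class TestTextCloudIO:
    def test_minimal_parse(self, tmp_path):
        path = tmp_path / "p.txt"
        path.write_text("0 0 0\n1 0 0\n0 1 0\n")
        cloud = read_cloud(path, format="xyz-text", column_map={"x": 0, "y": 1, "z": 2})
        assert len(cloud) == 3
        assert cloud.temperature is None and cloud.class_label is None

    def test_kelvin_passthrough(self, tmp_path):
        path = tmp_path / "p.txt"
        path.write_text("0 0 0 300.5\n1 1 1 301.5\n")
        cloud = read_cloud(path, format="xyz-text",
                           column_map={"x": 0, "y": 1, "z": 2, "temperature": 3},
                           temperature_unit="kelvin")
        assert cloud.temperature_unit == "kelvin"
        np.testing.assert_array_equal(cloud.temperature, [300.5, 301.5])

    def test_roundtrip_with_scalar(self, tmp_path):
        cloud = AttributedPointCloud(
            coords=np.random.default_rng(1).uniform(0, 100, (20, 3)),
            temperature=np.linspace(20, 40, 20), temperature_unit="celsius",
            class_label=np.array(["canopy"] * 20),
            scalars={"cwsi": np.linspace(0, 1, 20)})
        path = tmp_path / "c.txt"
        write_cloud(cloud, path, format="xyz-text")
        back = read_cloud(path, format="xyz-text")
        np.testing.assert_allclose(back.coords, cloud.coords, atol=1e-6)
        np.testing.assert_allclose(back.scalars["cwsi"], cloud.scalars["cwsi"], atol=1e-8)
        assert back.temperature_unit == "celsius"
        assert list(back.class_label) == ["canopy"] * 20

    def test_empty_cloud_roundtrip(self, tmp_path):
        cloud = AttributedPointCloud(coords=np.zeros((0, 3)))
        path = tmp_path / "e.txt"
        write_cloud(cloud, path, format="xyz-text")
        back = read_cloud(path, format="xyz-text")
        assert len(back) == 0

    def test_ragged_rows_rejected(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("0 0 0\n1 0\n")
        with pytest.raises(ContractError):
            read_cloud(path, format="xyz-text", column_map={"x": 0, "y": 1, "z": 2})

    def test_non_numeric_rejected(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("0 0 zero\n")
        with pytest.raises(ContractError):
            read_cloud(path, format="xyz-text", column_map={"x": 0, "y": 1, "z": 2})

    def test_unknown_format(self, tmp_path):
        path = tmp_path / "p.txt"
        path.write_text("0 0 0\n")
        with pytest.raises(ContractError, match="format"):
            read_cloud(path, format="e57")

    def test_comma_delimited(self, tmp_path):
        path = tmp_path / "p.csv"
        path.write_text("0,0,0\n1,2,3\n")
        cloud = read_cloud(path, format="xyz-text", column_map={"x": 0, "y": 1, "z": 2})
        np.testing.assert_array_equal(cloud.coords[1], [1, 2, 3])


class TestLasIO:
    def test_class_code_mapping(self, tmp_path):
        cloud = AttributedPointCloud(
            coords=np.array([[0.0, 0.0, 0.0], [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]]),
            class_label=np.array(["ground", "canopy", "noise"]))
        path = tmp_path / "c.las"
        write_cloud(cloud, path, format="las")
        back = read_cloud(path, format="las")
        assert list(back.class_label) == ["ground", "canopy", "noise"]
        np.testing.assert_allclose(back.coords, cloud.coords, atol=1e-6)

    def test_unsupported_attribute_errors(self, tmp_path):
        cloud = AttributedPointCloud(coords=np.zeros((2, 3)),
                                     temperature=[1.0, 2.0], temperature_unit="celsius")
        with pytest.raises(ContractError, match="temperature"):
            write_cloud(cloud, tmp_path / "c.las", format="las")
        # drop_unsupported writes coordinates only
        write_cloud(cloud, tmp_path / "c.las", format="las", drop_unsupported=True)
        back = read_cloud(tmp_path / "c.las", format="las")
        assert back.temperature is None and len(back) == 2

    def test_empty_las(self, tmp_path):
        cloud = AttributedPointCloud(coords=np.zeros((0, 3)))
        write_cloud(cloud, tmp_path / "e.las", format="las")
        back = read_cloud(tmp_path / "e.las", format="las")
        assert len(back) == 0


class TestPlyIO:
    @pytest.mark.parametrize("binary", [False, True])
    def test_coordinate_roundtrip_tolerance(self, tmp_path, binary):
        rng = np.random.default_rng(2)
        cloud = AttributedPointCloud(coords=rng.uniform(0, 500, (50, 3)),
                                     temperature=rng.uniform(290, 320, 50),
                                     temperature_unit="kelvin",
                                     color=rng.integers(0, 256, (50, 3)),
                                     scalars={"cwsi": rng.uniform(-0.2, 1.2, 50)})
        path = tmp_path / "c.ply"
        write_cloud(cloud, path, format="ply", binary=binary)
        back = read_cloud(path, format="ply")
        assert np.abs(back.coords - cloud.coords).max() <= 1e-6
        assert back.temperature_unit == "kelvin"
        np.testing.assert_array_equal(back.color, cloud.color)
        np.testing.assert_allclose(back.scalars["cwsi"], cloud.scalars["cwsi"], atol=1e-9)


class TestRoiPolygon:
    def test_self_intersection_rejected(self):
        with pytest.raises(ContractError):
            RoiPolygon(vertices=[(0, 0), (1, 1), (1, 0), (0, 1)])  # bow-tie

    def test_area(self):
        roi = RoiPolygon(vertices=[(0, 0), (2, 0), (2, 3), (0, 3)])
        assert roi.area == pytest.approx(6.0)
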