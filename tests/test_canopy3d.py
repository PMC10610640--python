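import numpy as np
import pytest

from vinecwsi.canopy3d import (
    GroundClassifierParams,
    NoiseFilterParams,
    TerrainSurface,
    classify_ground,
    filter_noise,
    remove_understory,
    segment_top,
    trim_bottom,
)
from vinecwsi.errors import ContractError, DegenerateGeometryError
from vinecwsi.geodata import AttributedPointCloud
from vinecwsi.synthetic import SceneConfig, generate_scene


def plane_cloud(n_elevated=50, tilt=0.0, seed=0, height=1.5):
    """Truth-labeled cloud: a gridded plane floor plus random elevated points.

    The floor grid guarantees at least one true ground point per 1 m seed
    cell, as a continuously sampled vineyard floor would.
    """
    rng = np.random.default_rng(seed)
    gx, gy = np.meshgrid(np.linspace(0, 10, 15), np.linspace(0, 10, 15))
    gxy = np.column_stack([gx.ravel(), gy.ravel()])
    interior = (gxy > 0.5).all(axis=1) & (gxy < 9.5).all(axis=1)
    gxy[interior] += rng.uniform(-0.2, 0.2, (int(interior.sum()), 2))
    gz = np.tan(np.radians(tilt)) * gxy[:, 0]
    exy = rng.uniform(1, 9, (n_elevated, 2))
    ez = np.tan(np.radians(tilt)) * exy[:, 0] + height
    coords = np.vstack([np.column_stack([gxy, gz]), np.column_stack([exy, ez])])
    labels = np.array(["ground"] * len(gxy) + ["canopy"] * n_elevated, dtype="U10")
    return AttributedPointCloud(coords=coords, class_label=labels)


class TestClassifyGround:
    def test_flat_plane_with_elevated_points(self):
        truth = plane_cloud()
        out = classify_ground(AttributedPointCloud(coords=truth.coords))
        assert (out.class_label == truth.class_label).all()

    def test_tilted_plane_recall(self):
        truth = plane_cloud(tilt=5.0, seed=1)
        out = classify_ground(AttributedPointCloud(coords=truth.coords))
        ground_truth = truth.class_label == "ground"
        recall = np.mean(out.class_label[ground_truth] == "ground")
        assert recall >= 0.99

    def test_two_points_error(self):
        with pytest.raises(DegenerateGeometryError):
            classify_ground(AttributedPointCloud(coords=[[0, 0, 0], [1, 1, 1]]))

    def test_collinear_error(self):
        coords = np.column_stack([np.arange(10.0), np.arange(10.0), np.zeros(10)])
        with pytest.raises(DegenerateGeometryError):
            classify_ground(AttributedPointCloud(coords=coords))

    def test_partition_complete(self, small_scene):
        out = classify_ground(small_scene.cloud)
        assert set(np.unique(out.class_label)) <= {"ground", "canopy"}
        assert len(out) == len(small_scene.cloud)

    def test_accuracy_across_seeds_flat_and_sloped(self):
        """>= 95% ground/canopy label accuracy vs synthetic truth, 10 seeds."""
        for slope in ((0.0, 0.0), (np.tan(np.radians(5.0)), 0.0)):
            for seed in range(10):
                cfg = SceneConfig(n_rows=2, plants_per_row=3, point_density=100.0,
                                  ground_point_density=12.0, terrain_slope=slope,
                                  cell_size=0.5, seed=seed)
                scene = generate_scene(cfg)
                out = classify_ground(scene.cloud)
                acc = np.mean(out.class_label == scene.cloud.class_label)
                assert acc >= 0.95, f"slope={slope} seed={seed}: accuracy {acc:.3f}"

    def test_preserves_order_and_attributes(self, small_scene):
        out = classify_ground(small_scene.cloud)
        np.testing.assert_array_equal(out.coords, small_scene.cloud.coords)
        np.testing.assert_array_equal(out.temperature, small_scene.cloud.temperature)


class TestFilterNoise:
    def test_gross_outlier_removed(self):
        gx, gy = np.meshgrid(np.arange(10.0), np.arange(10.0))
        coords = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(100)])
        coords = np.vstack([coords, [[5.0, 5.0, 100.0]]])
        cloud = AttributedPointCloud(coords=coords)
        out = filter_noise(cloud)
        assert len(out) == 100
        assert out.z.max() == 0.0

    def test_permissive_limit_removes_nothing(self):
        rng = np.random.default_rng(4)
        cloud = AttributedPointCloud(coords=rng.uniform(0, 5, (200, 3)))
        params = NoiseFilterParams(sigma_multiplier=1e6)
        out = filter_noise(cloud, params)
        assert len(out) == 200
        # idempotent in the permissive limit
        assert len(filter_noise(out, params)) == 200

    def test_labeled_simulation(self):
        """Gaussian cluster with implanted far outliers: >=9/10 removed, <=2% inliers lost."""
        rng = np.random.default_rng(5)
        inliers = rng.normal(0, 1, (1000, 3))
        outliers = rng.uniform(40, 60, (10, 3)) * rng.choice([-1, 1], (10, 3))
        cloud = AttributedPointCloud(coords=np.vstack([inliers, outliers]))
        retained, removed = filter_noise(cloud, return_removed=True)
        removed_outliers = np.sum(np.abs(removed.coords).max(axis=1) >= 40)
        inliers_lost = len(removed) - removed_outliers
        assert removed_outliers >= 9
        assert inliers_lost <= 0.02 * 1000
        assert (removed.class_label == "noise").all()

    def test_too_few_points_error(self):
        cloud = AttributedPointCloud(coords=np.zeros((5, 3)))
        with pytest.raises(ContractError):
            filter_noise(cloud, NoiseFilterParams(k_neighbors=8))

    def test_param_validation(self):
        with pytest.raises(ContractError):
            NoiseFilterParams(k_neighbors=0)
        with pytest.raises(ContractError):
            NoiseFilterParams(sigma_multiplier=0)


def flat_surface():
    return TerrainSurface(np.array([[0, 0, 0], [20, 0, 0], [0, 20, 0], [20, 20, 0.0]]))


class TestRemoveUnderstory:
    def test_trunk_points_removed(self):
        coords = np.array([[5, 5, 0.2], [5, 6, 1.0], [6, 5, 0.49], [6, 6, 0.5]])
        cloud = AttributedPointCloud(coords=coords)
        out = remove_understory(cloud, flat_surface(), min_height=0.5)
        np.testing.assert_array_equal(out.z, [1.0, 0.5])

    def test_zero_min_height_identity_inside_hull(self):
        rng = np.random.default_rng(6)
        coords = rng.uniform((1, 1, 0), (19, 19, 3), (100, 3))
        cloud = AttributedPointCloud(coords=coords)
        out = remove_understory(cloud, flat_surface(), min_height=0.0)
        assert len(out) == 100

    def test_outside_hull_dropped(self):
        cloud = AttributedPointCloud(coords=[[100.0, 100.0, 5.0], [5.0, 5.0, 1.0]])
        out = remove_understory(cloud, flat_surface(), min_height=0.5)
        assert len(out) == 1

    def test_synthetic_scene_purity(self, default_scene):
        """>= 98% of surviving points are truth-labeled canopy."""
        scene = default_scene
        classified = classify_ground(scene.cloud)
        surface = TerrainSurface.from_ground(classified)
        candidate = classified.subset(classified.class_label == "canopy")
        truth = scene.cloud.class_label[classified.class_label == "canopy"]
        out = remove_understory(candidate.with_scalar("row", np.arange(len(candidate))),
                                surface, min_height=0.5)
        survivors = out.scalars["row"].astype(int)
        purity = np.mean(truth[survivors] == "canopy")
        assert purity >= 0.98


class TestTrimBottom:
    def test_zero_trim_identity(self):
        rng = np.random.default_rng(7)
        cloud = AttributedPointCloud(coords=rng.uniform((1, 1, 0.5), (19, 19, 2), (50, 3)))
        out = trim_bottom(cloud, flat_surface(), 0.0)
        assert len(out) == 50

    def test_uniform_order_statistics(self):
        """Heights uniform on [0.5, 1.5], trim 0.2 -> about 80% retained."""
        rng = np.random.default_rng(8)
        n = 5000
        xy = rng.uniform(1, 19, (n, 2))
        z = rng.uniform(0.5, 1.5, n)
        cloud = AttributedPointCloud(coords=np.column_stack([xy, z]))
        out = trim_bottom(cloud, flat_surface(), 0.2)
        assert len(out) / n == pytest.approx(0.8, abs=0.03)

    def test_trim_exceeding_depth_warns_and_empties(self):
        cloud = AttributedPointCloud(coords=[[5, 5, 1.0], [6, 6, 1.1], [7, 7, 1.2]])
        with pytest.warns(UserWarning, match="exceeds"):
            out = trim_bottom(cloud, flat_surface(), 5.0)
        assert len(out) == 0

    def test_negative_trim_rejected(self):
        cloud = AttributedPointCloud(coords=[[5, 5, 1.0]])
        with pytest.raises(ContractError):
            trim_bottom(cloud, flat_surface(), -0.1)


class TestSegmentTop:
    def test_window_within_cell(self):
        coords = np.array([[0.1, 0.1, 1.0], [0.11, 0.12, 1.5], [0.12, 0.11, 2.0]])
        cloud = AttributedPointCloud(coords=coords)
        out = segment_top(cloud, cell_size=0.25, depth_m=0.2)
        np.testing.assert_array_equal(out.z, [2.0])

    def test_depth_covering_whole_canopy_is_identity(self):
        rng = np.random.default_rng(9)
        cloud = AttributedPointCloud(coords=rng.uniform(0, 3, (200, 3)))
        out = segment_top(cloud, cell_size=0.25, depth_m=10.0)
        assert len(out) == 200

    def test_invalid_params(self):
        cloud = AttributedPointCloud(coords=np.zeros((1, 3)))
        with pytest.raises(ContractError):
            segment_top(cloud, cell_size=0.0)
        with pytest.raises(ContractError):
            segment_top(cloud, depth_m=-1.0)

    def test_subset_and_monotone_in_depth(self):
        rng = np.random.default_rng(10)
        cloud = AttributedPointCloud(coords=rng.uniform(0, 5, (500, 3)),
                                     scalars={"row": np.arange(500.0)})
        prev = set()
        for depth in (0.1, 0.5, 1.0, 5.0):
            out = segment_top(cloud, depth_m=depth)
            rows = set(out.scalars["row"].astype(int))
            assert prev <= rows
            prev = rows
        assert prev == set(range(500))

    def test_top_cooler_than_full_canopy_with_gradient(self, default_scene):
        """Positive vertical gradient: the segmented top is cooler on average."""
        scene = default_scene
        canopy = scene.cloud.subset(scene.cloud.class_label == "canopy")
        top = segment_top(canopy)
        assert top.temperature.mean() < canopy.temperature.mean()
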