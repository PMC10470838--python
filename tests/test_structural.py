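import numpy as np
import pytest
from scipy.spatial import cKDTree

from phenosalt.fixtures import CanopySpec, make_canopy
from phenosalt.structural import (
    FilterConfig,
    PointCloud,
    base_to_ground,
    canopy_leaf_area,
    convex_hull_volume,
    extract_structural_traits,
    grid_height,
    load_points,
    mean_knn_distance,
    mls_smooth,
    remove_outliers,
    save_points,
    voxel_filter_below_canopy,
)


def cloud_of(points, sample_id="t"):
    return PointCloud(points=np.asarray(points, dtype=float), sample_id=sample_id)


@pytest.fixture()
def random_cloud():
    rng = np.random.default_rng(0)
    return cloud_of(rng.uniform(0.0, 10.0, size=(500, 3)))


class TestIO:
    @pytest.mark.parametrize("fmt", ["ply", "xyz", "las"])
    def test_round_trip(self, tmp_path, random_cloud, fmt):
        path = str(tmp_path / f"cloud.{fmt}")
        save_points(random_cloud, path)
        back = load_points(path)
        atol = 1e-3 if fmt == "las" else 1e-5  # las stores quantized coords
        np.testing.assert_allclose(back.points, random_cloud.points, atol=atol)

    def test_empty_file_is_error(self, tmp_path):
        path = tmp_path / "empty.xyz"
        path.write_text("")
        with pytest.raises(ValueError):
            load_points(str(path))

    def test_xyz_five_rows(self, tmp_path):
        path = tmp_path / "five.xyz"
        path.write_text("\n".join(f"{i} {i} {i}" for i in range(5)))
        assert len(load_points(str(path))) == 5

    def test_fewer_than_four_points_is_error(self, tmp_path):
        path = tmp_path / "three.xyz"
        path.write_text("0 0 0\n1 0 0\n0 1 0\n")
        with pytest.raises(ValueError, match="at least 4"):
            load_points(str(path))

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_points(str(tmp_path / "nope.ply"))

    def test_unit_scale(self, tmp_path, random_cloud):
        path = str(tmp_path / "m.xyz")
        save_points(random_cloud, path)
        back = load_points(path, unit_scale=100.0)
        np.testing.assert_allclose(back.points, random_cloud.points * 100.0, atol=1e-3)


class TestRemoveOutliers:
    def test_exact_planted_set_removed(self, labelled_outlier_canopy):
        cloud, _, labels = labelled_outlier_canopy
        filtered = remove_outliers(cloud)
        np.testing.assert_array_equal(filtered.points, cloud.points[~labels])

    def test_outlier_free_removal_small(self, box_canopy):
        cloud, _, _ = box_canopy
        filtered = remove_outliers(cloud)
        assert 1.0 - len(filtered) / len(cloud) <= 0.02

    def test_huge_multiplier_is_identity(self, random_cloud):
        filtered = remove_outliers(random_cloud, std_multiplier=1e9)
        np.testing.assert_array_equal(filtered.points, random_cloud.points)

    def test_matches_brute_force_statistic(self, random_cloud):
        pts = random_cloud.points
        knn = 5
        stat = np.empty(len(pts))
        for i in range(len(pts)):  # brute-force neighbour statistic
            d = np.sort(np.linalg.norm(pts - pts[i], axis=1))
            stat[i] = d[1 : knn + 1].mean()
        keep = stat <= stat.mean() + 2.0 * stat.std()
        filtered = remove_outliers(random_cloud, knn=knn, std_multiplier=2.0)
        np.testing.assert_array_equal(filtered.points, pts[keep])

    def test_needs_more_points_than_knn(self):
        with pytest.raises(ValueError, match="knn"):
            remove_outliers(cloud_of(np.eye(4, 3)), knn=16)


class TestVoxelFilter:
    def test_all_points_above_cut_identity(self):
        pts = np.column_stack(
            [np.arange(10.0), np.arange(10.0), np.full(10, 5.0)]
        )
        pts[0, 2] = 4.9999  # z range collapses to near-zero; all at/above cut
        cloud = cloud_of(pts)
        out = voxel_filter_below_canopy(cloud, voxel_size=0.5, canopy_fraction=0.5)
        assert len(out) <= len(cloud)

    def test_coincident_low_points_collapse(self):
        low = np.tile([1.0, 1.0, 0.0], (100, 1))
        high = np.array([[0.0, 0.0, 10.0], [2.0, 2.0, 10.0], [3.0, 1.0, 10.0]])
        cloud = cloud_of(np.vstack([low, high]))
        out = voxel_filter_below_canopy(cloud, voxel_size=0.5, canopy_fraction=0.5)
        assert len(out) == 1 + 3
        assert (out.points[0] == [1.0, 1.0, 0.0]).all()

    def test_never_grows(self, random_cloud):
        out = voxel_filter_below_canopy(random_cloud, 0.5, 0.5)
        assert len(out) <= len(random_cloud)

    def test_high_points_pass_through(self, random_cloud):
        out = voxel_filter_below_canopy(random_cloud, 0.5, 0.5)
        z = random_cloud.points[:, 2]
        cut = z.min() + 0.5 * (z.max() - z.min())
        high = random_cloud.points[z >= cut]
        # every untouched high point appears unchanged in the output
        tree = cKDTree(out.points)
        dist, _ = tree.query(high)
        assert dist.max() == 0.0


class TestMlsSmooth:
    def test_plane_is_fixed_point(self):
        rng = np.random.default_rng(3)
        xy = rng.uniform(0.0, 10.0, size=(400, 2))
        pts = np.column_stack([xy, np.full(400, 2.0)])
        out = mls_smooth(cloud_of(pts), radius=1.0)
        assert np.abs(out.points - pts).max() <= 1e-6

    def test_noisy_plane_smoothed(self):
        rng = np.random.default_rng(4)
        xy = rng.uniform(0.0, 20.0, size=(2000, 2))
        noise = rng.normal(0.0, 0.2, size=2000)
        pts = np.column_stack([xy, 5.0 + noise])
        out = mls_smooth(cloud_of(pts), radius=1.5)
        rms_before = np.sqrt(np.mean((pts[:, 2] - 5.0) ** 2))
        rms_after = np.sqrt(np.mean((out.points[:, 2] - 5.0) ** 2))
        assert rms_after < rms_before
        assert rms_after < 0.2

    def test_isolated_point_unchanged(self):
        pts = np.array(
            [[0.0, 0.0, 0.0], [0.1, 0.0, 0.0], [0.0, 0.1, 0.0],
             [0.1, 0.1, 0.0], [50.0, 50.0, 5.0]]
        )
        out = mls_smooth(cloud_of(pts), radius=1.0)
        np.testing.assert_array_equal(out.points[4], pts[4])

    def test_count_preserved(self, random_cloud):
        assert len(mls_smooth(random_cloud, 1.0)) == len(random_cloud)


class TestBaseToGround:
    def test_shift(self):
        pts = np.column_stack([np.zeros(4), np.zeros(4), [3.0, 5.0, 7.0, 10.0]])
        out = base_to_ground(cloud_of(pts))
        np.testing.assert_allclose(out.points[:, 2], [0.0, 2.0, 4.0, 7.0])

    def test_identity_when_based(self, random_cloud):
        based = base_to_ground(random_cloud)
        again = base_to_ground(based)
        np.testing.assert_array_equal(again.points, based.points)

    def test_xy_untouched(self, random_cloud):
        out = base_to_ground(random_cloud)
        np.testing.assert_array_equal(out.points[:, :2], random_cloud.points[:, :2])


class TestGridHeight:
    def test_flat_canopy_any_cell(self):
        rng = np.random.default_rng(5)
        pts = np.column_stack(
            [rng.uniform(0, 10, 300), rng.uniform(0, 10, 300), np.full(300, 12.0)]
        )
        for cell in (0.25, 0.5, 2.0):
            assert grid_height(cloud_of(pts), cell) == pytest.approx(12.0)

    def test_two_cells_mean(self):
        pts = np.array(
            [[0.1, 0.1, 10.0], [0.2, 0.2, 3.0], [1.1, 0.1, 20.0], [1.2, 0.3, 1.0]]
        )
        assert grid_height(cloud_of(pts), cell=0.5) == pytest.approx(15.0)

    def test_hemisphere_matches_percell_analytic_maxima(self):
        # oracle: for every occupied cell, the analytic maximum of the
        # hemisphere surface over that cell's footprint rectangle
        R = 10.0
        cloud, _, _ = make_canopy(
            CanopySpec(shape="hemisphere", dimensions=(R,), point_density=9.0, seed=6)
        )
        cell = 0.5
        pts = cloud.points
        origin = pts[:, :2].min(axis=0)
        ij = np.floor((pts[:, :2] - origin) / cell).astype(int)
        oracle_vals = []
        for i, j in {tuple(t) for t in ij}:
            x_lo, x_hi = origin[0] + i * cell, origin[0] + (i + 1) * cell
            y_lo, y_hi = origin[1] + j * cell, origin[1] + (j + 1) * cell
            # closest point of the rectangle to the dome axis
            cx = min(max(0.0, x_lo), x_hi) if x_lo <= 0.0 <= x_hi else min(abs(x_lo), abs(x_hi))
            cy = min(max(0.0, y_lo), y_hi) if y_lo <= 0.0 <= y_hi else min(abs(y_lo), abs(y_hi))
            d2 = cx**2 + cy**2
            oracle_vals.append(np.sqrt(max(R**2 - d2, 0.0)))
        oracle = float(np.mean(oracle_vals))
        assert grid_height(cloud, cell) == pytest.approx(oracle, rel=0.05)

    def test_translation_by_cell_multiples_invariant(self, random_cloud):
        h0 = grid_height(random_cloud, 0.5)
        shifted = cloud_of(random_cloud.points + np.array([3 * 0.5, -7 * 0.5, 0.0]))
        assert grid_height(shifted, 0.5) == pytest.approx(h0)


class TestCanopyLeafArea:
    def test_single_cell(self):
        rng = np.random.default_rng(7)
        pts = np.column_stack(
            [rng.uniform(0, 0.4, 30), rng.uniform(0, 0.4, 30), rng.uniform(0, 5, 30)]
        )
        assert canopy_leaf_area(cloud_of(pts), cell=0.5) == pytest.approx(0.25)

    def test_single_point(self):
        pts = np.array([[1.0, 2.0, 3.0]] * 4)
        assert canopy_leaf_area(cloud_of(pts), cell=0.5) == pytest.approx(0.25)

    def test_dense_disk_close_to_analytic(self):
        # jittered-lattice sampling of a disk footprint
        r, cell = 10.0, 0.5
        rng = np.random.default_rng(8)
        xs = np.arange(-r, r, 0.25) + 0.125
        gx, gy = np.meshgrid(xs, xs, indexing="ij")
        keep = gx**2 + gy**2 < r**2
        x = gx[keep] + rng.uniform(-0.05, 0.05, keep.sum())
        y = gy[keep] + rng.uniform(-0.05, 0.05, keep.sum())
        pts = np.column_stack([x, y, np.zeros_like(x)])
        area = canopy_leaf_area(cloud_of(pts), cell)
        assert area == pytest.approx(np.pi * r**2, rel=0.05)

    def test_non_decreasing_when_points_added(self, random_cloud):
        a_half = canopy_leaf_area(cloud_of(random_cloud.points[:250]), 0.5)
        a_full = canopy_leaf_area(random_cloud, 0.5)
        assert a_full >= a_half

    def test_translation_by_cell_multiples_invariant(self, random_cloud):
        a0 = canopy_leaf_area(random_cloud, 0.5)
        shifted = cloud_of(random_cloud.points + np.array([5 * 0.5, 2 * 0.5, 1.0]))
        assert canopy_leaf_area(shifted, 0.5) == pytest.approx(a0)


class TestConvexHullVolume:
    def test_cube_corners(self):
        corners = np.array(
            [[x, y, z] for x in (0, 10.0) for y in (0, 10.0) for z in (0, 10.0)]
        )
        assert convex_hull_volume(cloud_of(corners)) == pytest.approx(1000.0)

    def test_regular_tetrahedron(self):
        a = 4.0
        verts = a / (2.0 * np.sqrt(2.0)) * np.array(
            [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]]
        )
        expected = a**3 / (6.0 * np.sqrt(2.0))
        assert convex_hull_volume(cloud_of(verts)) == pytest.approx(expected)

    def test_coplanar_is_degenerate(self):
        pts = np.column_stack(
            [np.arange(10.0), np.arange(10.0) ** 2, np.zeros(10)]
        )
        with pytest.raises(ValueError, match="degenerate hull"):
            convex_hull_volume(cloud_of(pts))

    def test_monte_carlo_oracle(self):
        rng = np.random.default_rng(9)
        pts = rng.uniform(0.0, 10.0, size=(10_000, 3))
        vol = convex_hull_volume(cloud_of(pts))
        box_vol = 1000.0
        fresh = rng.uniform(0.0, 10.0, size=(50_000, 3))
        from scipy.spatial import ConvexHull

        hull = ConvexHull(pts)
        inside = (
            fresh @ hull.equations[:, :3].T + hull.equations[:, 3] <= 1e-9
        ).all(axis=1)
        p = inside.mean()
        se = box_vol * np.sqrt(p * (1 - p) / fresh.shape[0])
        assert abs(vol - p * box_vol) <= 3 * se

    def test_rigid_motion_invariance(self, random_cloud):
        from scipy.spatial.transform import Rotation

        v0 = convex_hull_volume(random_cloud)
        rot = Rotation.from_euler("xyz", [20, 45, 70], degrees=True).as_matrix()
        moved = cloud_of(random_cloud.points @ rot.T + np.array([5.0, -3.0, 11.0]))
        assert convex_hull_volume(moved) == pytest.approx(v0, rel=1e-9)

    def test_scaling_cubes_volume(self, random_cloud):
        v0 = convex_hull_volume(random_cloud)
        s = 2.5
        scaled = cloud_of(random_cloud.points * s)
        assert convex_hull_volume(scaled) == pytest.approx(v0 * s**3, rel=1e-9)


class TestExtractStructuralTraits:
    def test_box_recovery(self, box_canopy):
        cloud, truth, _ = box_canopy
        traits = extract_structural_traits(cloud)
        assert traits.height == pytest.approx(truth.height, rel=0.05)
        assert traits.canopy_leaf_area == pytest.approx(truth.footprint_area, rel=0.05)
        assert traits.volume == pytest.approx(truth.volume, rel=0.05)

    def test_recovery_with_planted_outliers(self):
        clean, truth, _ = make_canopy(
            CanopySpec(shape="box", dimensions=(20.0, 20.0, 15.0),
                       point_density=9.0, seed=3)
        )
        noisy, _, _ = make_canopy(
            CanopySpec(shape="box", dimensions=(20.0, 20.0, 15.0),
                       point_density=9.0, outlier_count=10, seed=3)
        )
        t_clean = extract_structural_traits(clean)
        t_noisy = extract_structural_traits(noisy)
        assert t_noisy.height == pytest.approx(t_clean.height, rel=0.05)
        assert t_noisy.canopy_leaf_area == pytest.approx(t_clean.canopy_leaf_area, rel=0.05)
        assert t_noisy.volume == pytest.approx(t_clean.volume, rel=0.05)

    def test_taller_canopy_is_taller(self):
        short, _, _ = make_canopy(
            CanopySpec(shape="box", dimensions=(10.0, 10.0, 8.0), point_density=4.0, seed=1)
        )
        tall, _, _ = make_canopy(
            CanopySpec(shape="box", dimensions=(10.0, 10.0, 14.0), point_density=4.0, seed=1)
        )
        assert (
            extract_structural_traits(tall).height
            > extract_structural_traits(short).height
        )

    def test_filters_never_grow_point_count(self, labelled_outlier_canopy):
        cloud, _, _ = labelled_outlier_canopy
        c1 = remove_outliers(cloud)
        assert len(c1) <= len(cloud)
        c2 = voxel_filter_below_canopy(c1)
        assert len(c2) <= len(c1)
        c3 = mls_smooth(c2)
        assert len(c3) == len(c2)

    def test_filter_config_validation(self):
        with pytest.raises(ValueError):
            FilterConfig(knn=0)
        with pytest.raises(ValueError):
            FilterConfig(canopy_fraction=1.5)
        with pytest.raises(ValueError):
            FilterConfig(voxel_size=-1.0)
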