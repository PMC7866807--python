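import numpy as np
import pytest

from plantarseg import (CameraModel, DegenerateInputError, NoPlaneError,
                        ParameterError, Plane, PointCloud, RansacConfig,
                        StatFilterConfig, auto_distance_threshold, dice,
                        mask_to_pointcloud, ransac_plane, refine_mask,
                        segment_spd, statistical_outlier_filter)
from plantarseg.depth import export_ply
from plantarseg.frames import DEFAULT_IR_CAMERA
from plantarseg.synthetic import SceneConfig, generate_scene

from conftest import make_mask

CAM = CameraModel(width=64, height=48, fx=100.0, fy=120.0, cx=32.0, cy=24.0)


def grid_cloud(nx=30, ny=30, z=800.0, spacing=5.0):
    yy, xx = np.mgrid[0:ny, 0:nx]
    pts = np.column_stack([xx.ravel() * spacing, yy.ravel() * spacing,
                           np.full(nx * ny, z)])
    return PointCloud(points=pts, pixel_index=np.column_stack(
        [yy.ravel(), xx.ravel()]))


class TestDeprojection:
    def test_principal_point_ray(self):
        data = np.zeros((48, 64), dtype=np.uint8)
        data[24, 32] = 1
        depth = np.zeros((48, 64), dtype=np.uint16)
        depth[24, 32] = 800
        pc = mask_to_pointcloud(make_mask(data), depth, CAM)
        np.testing.assert_allclose(pc.points, [[0.0, 0.0, 800.0]])

    def test_off_center_pinhole_formula(self):
        # pixel (row 10, col 50), z = 1000:
        # x = (50-32)*1000/100 = 180 ; y = (10-24)*1000/120 = -116.666..
        data = np.zeros((48, 64), dtype=np.uint8)
        data[10, 50] = 1
        depth = np.zeros((48, 64), dtype=np.uint16)
        depth[10, 50] = 1000
        pc = mask_to_pointcloud(make_mask(data), depth, CAM)
        np.testing.assert_allclose(pc.points,
                                   [[180.0, -1000 * 14 / 120, 1000.0]])

    def test_constant_depth_shares_z_and_records_invalid(self):
        data = np.ones((4, 5), dtype=np.uint8)
        depth = np.full((4, 5), 750, dtype=np.uint16)
        depth[2, 2] = 0  # invalid measurement
        pc = mask_to_pointcloud(make_mask(data), depth, CAM)
        assert len(pc) == 19
        assert set(pc.points[:, 2]) == {750.0}
        np.testing.assert_array_equal(pc.undeprojectable, [[2, 2]])

    def test_no_valid_depth_is_degenerate(self):
        data = np.ones((3, 3), dtype=np.uint8)
        with pytest.raises(DegenerateInputError):
            mask_to_pointcloud(make_mask(data),
                               np.zeros((3, 3), dtype=np.uint16), CAM)


class TestStatisticalFilter:
    def test_isolated_point_removed(self):
        pc = grid_cloud()
        far = np.vstack([pc.points, [[500.0, 500.0, 900.0]]])
        idx = np.vstack([pc.pixel_index, [[40, 40]]])
        noisy = PointCloud(points=far, pixel_index=idx)
        filtered = statistical_outlier_filter(noisy, StatFilterConfig())
        assert len(filtered) == len(pc)
        assert not (filtered.pixel_index == [40, 40]).all(axis=1).any()

    def test_equidistant_points_untouched(self):
        # regular polygon with k=2: every per-point mean kNN distance is
        # identical, so the zero-variance cutoff removes nothing
        theta = np.linspace(0, 2 * np.pi, 24, endpoint=False)
        pts = np.column_stack([100 * np.cos(theta), 100 * np.sin(theta),
                               np.full(24, 800.0)])
        pc = PointCloud(points=pts, pixel_index=np.column_stack(
            [np.arange(24), np.zeros(24, int)]))
        filtered = statistical_outlier_filter(
            pc, StatFilterConfig(k_neighbors=2))
        assert len(filtered) == 24

    def test_grid_interior_survives_edge_attrition(self):
        # on a finite uniform grid only the boundary ring has elevated
        # neighbour distances; the interior must never be removed
        pc = grid_cloud()
        filtered = statistical_outlier_filter(pc, StatFilterConfig())
        kept = set(map(tuple, filtered.pixel_index))
        interior = {(r, c) for r in range(5, 25) for c in range(5, 25)}
        assert interior <= kept

    def test_huge_multiplier_is_identity(self, rng):
        pts = rng.normal(0, 100, (200, 3)) + [0, 0, 800]
        pc = PointCloud(points=pts, pixel_index=np.column_stack(
            [np.arange(200) // 20, np.arange(200) % 20]))
        filtered = statistical_outlier_filter(
            pc, StatFilterConfig(std_multiplier=1e9))
        assert len(filtered) == 200

    def test_too_few_points_is_degenerate(self):
        pc = grid_cloud(nx=3, ny=3)
        with pytest.raises(DegenerateInputError):
            statistical_outlier_filter(pc, StatFilterConfig(k_neighbors=20))


class TestRansacPlane:
    def test_exactly_coplanar_points_zero_residual(self, rng):
        xy = rng.uniform(-200, 200, (100, 2))
        normal = np.array([0.2, -0.1, 0.97])
        normal /= np.linalg.norm(normal)
        d = 780.0
        z = (d - xy @ normal[:2]) / normal[2]
        pc = PointCloud(points=np.column_stack([xy, z]),
                        pixel_index=np.column_stack(
                            [np.arange(100) // 10, np.arange(100) % 10]))
        plane, inliers = ransac_plane(pc, RansacConfig(seed=3), 1.0)
        assert len(inliers) == 100
        assert plane.distance(pc.points).max() < 1e-8

    def test_three_points_unique_plane(self):
        pts = np.array([[0, 0, 800], [100, 0, 810], [0, 100, 790]], float)
        pc = PointCloud(points=pts, pixel_index=[[0, 0], [0, 1], [1, 0]])
        plane, inliers = ransac_plane(pc, RansacConfig(seed=0), 0.5)
        assert len(inliers) == 3
        assert plane.distance(pts).max() < 1e-9

    def test_seeded_runs_bit_stable(self, rng):
        pts = np.column_stack([rng.uniform(-300, 300, (500, 2)),
                               800 + rng.normal(0, 2, 500)])
        pc = PointCloud(points=pts, pixel_index=np.column_stack(
            [np.arange(500) // 25, np.arange(500) % 25]))
        cfg = RansacConfig(iterations=100, seed=11)
        p1, i1 = ransac_plane(pc, cfg, 4.0)
        p2, i2 = ransac_plane(pc, cfg, 4.0)
        np.testing.assert_array_equal(p1.normal, p2.normal)
        assert p1.d == p2.d
        np.testing.assert_array_equal(i1, i2)

    def test_rotation_equivariance(self, rng):
        pts = np.column_stack([rng.uniform(-300, 300, (400, 2)),
                               800 + rng.normal(0, 1, 400)])
        pc = PointCloud(points=pts, pixel_index=np.column_stack(
            [np.arange(400) // 20, np.arange(400) % 20]))
        theta = 0.3
        rot = np.array([[1, 0, 0],
                        [0, np.cos(theta), -np.sin(theta)],
                        [0, np.sin(theta), np.cos(theta)]])
        shift = np.array([0, 0, 500.0])  # keep z positive after rotation
        pc_rot = PointCloud(points=pts @ rot.T + shift,
                            pixel_index=pc.pixel_index)
        plane, _ = ransac_plane(pc, RansacConfig(seed=5), 3.0)
        plane_rot, _ = ransac_plane(pc_rot, RansacConfig(seed=5), 3.0)
        expected = rot @ plane.normal
        cosang = abs(expected @ plane_rot.normal)
        assert cosang > np.cos(np.deg2rad(0.5))

    def test_min_inliers_enforced(self, rng):
        pts = rng.uniform(0, 1000, (50, 3)) + [0, 0, 10]
        pc = PointCloud(points=pts, pixel_index=np.column_stack(
            [np.arange(50) // 10, np.arange(50) % 10]))
        with pytest.raises(NoPlaneError):
            ransac_plane(pc, RansacConfig(iterations=50, min_inliers=49,
                                          seed=0), 0.01)

    def test_collinear_cloud_has_no_plane(self):
        t = np.linspace(0, 100, 20)
        pts = np.column_stack([t, 2 * t, 800 + 0 * t])
        pc = PointCloud(points=pts, pixel_index=np.column_stack(
            [np.arange(20), np.zeros(20, int)]))
        with pytest.raises(NoPlaneError):
            ransac_plane(pc, RansacConfig(iterations=20, seed=0), 1.0)


class TestAutoThreshold:
    def test_constant_depth_gives_zero(self):
        depth = np.full((10, 10), 800, dtype=np.uint16)
        mask = make_mask(np.ones((10, 10)))
        assert auto_distance_threshold(depth, mask, 2.0) == 0.0

    def test_two_sigma_rule_on_gaussian_depth(self, rng):
        depth = np.clip(np.rint(rng.normal(800, 4, (50, 40))), 1,
                        65535).astype(np.uint16)
        mask = make_mask(np.ones((50, 40)))
        thr = auto_distance_threshold(depth, mask, 2.0)
        assert thr == pytest.approx(8.0, rel=0.10)
        plain = auto_distance_threshold(depth, mask, 2.0, robust=False)
        assert plain == pytest.approx(8.0, rel=0.10)

    def test_c_zero_gives_zero(self, rng):
        depth = np.clip(np.rint(rng.normal(800, 4, (20, 20))), 1,
                        65535).astype(np.uint16)
        assert auto_distance_threshold(depth, make_mask(np.ones((20, 20))),
                                       0.0) == 0.0

    def test_contamination_does_not_inflate_robust_spread(self, rng):
        # 10% of the candidate mask sits 500 mm behind the feet
        depth = np.clip(np.rint(rng.normal(800, 4, (40, 50))), 1,
                        65535).astype(np.uint16)
        depth[:4, :] = 1300
        thr = auto_distance_threshold(depth, make_mask(np.ones((40, 50))), 2.0)
        assert thr < 20.0
        plain = auto_distance_threshold(depth, make_mask(np.ones((40, 50))),
                                        2.0, robust=False)
        assert plain > 200.0

    def test_single_pixel_is_degenerate(self):
        depth = np.zeros((5, 5), dtype=np.uint16)
        depth[0, 0] = 800
        with pytest.raises(DegenerateInputError):
            auto_distance_threshold(depth, make_mask(np.ones((5, 5))), 2.0)


class TestRefineMask:
    def _planar_setup(self):
        data = np.ones((6, 8), dtype=np.uint8)
        depth = np.full((6, 8), 800, dtype=np.uint16)
        depth[1, 1] = 0
        mask = make_mask(data)
        pc = mask_to_pointcloud(mask, depth, CAM)
        plane = Plane(normal=np.array([0.0, 0.0, 1.0]), d=800.0)
        return mask, pc, plane

    def test_on_plane_cloud_keeps_all_but_invalid(self):
        mask, pc, plane = self._planar_setup()
        refined = refine_mask(mask, plane, pc, threshold_mm=5.0)
        expected = mask.data.copy()
        expected[1, 1] = 0
        np.testing.assert_array_equal(refined.data, expected)

    def test_keep_policy_preserves_invalid_pixels(self):
        mask, pc, plane = self._planar_setup()
        refined = refine_mask(mask, plane, pc, 5.0,
                              undeprojectable_policy="keep")
        np.testing.assert_array_equal(refined.data, mask.data)

    def test_neighbor_vote_readds_surrounded_invalid_pixel(self):
        mask, pc, plane = self._planar_setup()
        refined = refine_mask(mask, plane, pc, 5.0,
                              undeprojectable_policy="fill-by-neighbor-vote")
        assert refined.data[1, 1] == 1

    def test_infinite_threshold_limit(self):
        mask, pc, plane = self._planar_setup()
        refined = refine_mask(mask, plane, pc, 1e12)
        expected = mask.data.copy()
        expected[1, 1] = 0
        np.testing.assert_array_equal(refined.data, expected)

    def test_output_subset_of_input(self, rng):
        data = (rng.random((20, 20)) < 0.6).astype(np.uint8)
        depth = np.clip(rng.normal(800, 50, (20, 20)).round(), 1,
                        65535).astype(np.uint16)
        mask = make_mask(data)
        pc = mask_to_pointcloud(mask, depth, CAM)
        plane = Plane(normal=np.array([0.0, 0.0, 1.0]), d=800.0)
        for policy in ("drop", "keep", "fill-by-neighbor-vote"):
            refined = refine_mask(mask, plane, pc, 30.0, policy)
            assert not (refined.as_bool() & ~mask.as_bool()).any()

    def test_non_positive_threshold_rejected(self):
        mask, pc, plane = self._planar_setup()
        with pytest.raises(ParameterError):
            refine_mask(mask, plane, pc, 0.0)


class TestPlaneType:
    def test_canonical_non_negative_offset(self):
        p = Plane(normal=np.array([0.0, 0.0, -1.0]), d=-800.0)
        assert p.d == 800.0
        np.testing.assert_allclose(p.normal, [0, 0, 1])

    def test_non_unit_normal_rejected(self):
        with pytest.raises(ParameterError):
            Plane(normal=np.array([1.0, 1.0, 0.0]), d=5.0)


class TestSpdPipeline:
    def test_distractor_free_scene_refinement_is_noop(self):
        frame, gt = generate_scene(SceneConfig(
            seed=9, n_skin_distractors=0, n_warm_distractors=0))
        # disable the edge filter and widen the plane band: with nothing to
        # refine away the output must equal the raw skin mask (all depths
        # here are valid, so no invalid-depth pixels are dropped either)
        res = segment_spd(frame,
                          stat_cfg=StatFilterConfig(std_multiplier=1e9),
                          ransac_cfg=RansacConfig(seed=9,
                                                  distance_threshold_mm=60.0))
        assert np.array_equal(res.mask.data, res.skin.data)

    def test_distractor_scene_improves_dice(self, default_scene):
        frame, gt = default_scene
        res = segment_spd(frame, ransac_cfg=RansacConfig(seed=1))
        assert dice(gt, res.mask) > dice(gt, res.skin)

    def test_empty_skin_mask_reports_stage(self):
        frame, _ = generate_scene(SceneConfig(seed=4))
        dark = frame.rgb.copy()
        dark[:] = 0
        frame.rgb = dark
        with pytest.raises(DegenerateInputError, match="deproject"):
            segment_spd(frame)

    def test_ply_export(self, tmp_path):
        pc = grid_cloud(nx=3, ny=2)
        export_ply(pc, tmp_path / "cloud.ply")
        text = (tmp_path / "cloud.ply").read_text().splitlines()
        assert text[0] == "ply"
        assert "element vertex 6" in text[2]
        assert len(text) == 6 + 7
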