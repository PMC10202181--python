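"""Road extraction, discrete CVT via Lloyd's algorithm, and projections."""

import math

import numpy as np
import pytest

from cvta import road, robot, simulate
from conftest import random_blob_region


class TestBinarize:
    def test_noise_free_scene_recovered_exactly(self, plain_scene):
        _, img, truth = plain_scene
        mask = road.binarize_kmeans(img)
        np.testing.assert_array_equal(mask, truth)

    def test_color_swap_invariance(self):
        cfg = simulate.RoadSceneConfig(obstacle_rects=[(60, 60, 30, 20)])
        swapped = simulate.RoadSceneConfig(
            road_color=cfg.background_color,
            background_color=cfg.road_color,
            obstacle_rects=[(60, 60, 30, 20)],
        )
        m1 = road.binarize_kmeans(simulate.generate_road_scene(cfg)[0])
        m2 = road.binarize_kmeans(simulate.generate_road_scene(swapped)[0])
        np.testing.assert_array_equal(m1, m2)

    def test_uniform_image_rejected(self):
        img = np.full((20, 20, 3), 128, dtype=np.uint8)
        with pytest.raises(road.DegenerateImageError):
            road.binarize_kmeans(img)

    def test_noisy_scene_mostly_recovered(self):
        cfg = simulate.RoadSceneConfig(color_noise_sd=10.0, seed=5)
        img, truth = simulate.generate_road_scene(cfg)
        mask = road.binarize_kmeans(img)
        assert (mask == truth).mean() > 0.99


class TestDenoise:
    def test_isolated_speck_removed(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[10, 10] = True
        assert not road.denoise(mask, 3).any()

    def test_large_rectangle_unchanged(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[5:25, 5:25] = True
        np.testing.assert_array_equal(road.denoise(mask, 3), mask)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        mask = rng.random((40, 40)) > 0.4
        once = road.denoise(mask, 3)
        np.testing.assert_array_equal(road.denoise(once, 3), once)


class TestExtractRegion:
    def test_single_blob_at_anchor(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[6:, 3:8] = True
        region = road.extract_road_region(mask)
        np.testing.assert_array_equal(region.mask, mask)

    def test_only_anchored_component_kept(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[8:, 3:8] = True  # touches bottom-center
        mask[0:2, 0:2] = True  # distant blob
        region = road.extract_road_region(mask)
        assert region.mask[9, 5] and not region.mask[0, 0]
        assert region.n_pixels == 10

    def test_background_at_anchor_rejected(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[0:3, :] = True
        with pytest.raises(road.NoRoadFoundError):
            road.extract_road_region(mask)


class TestVoronoi:
    def test_single_generator_owns_everything(self):
        region = road.RoadRegion.from_mask(np.ones((6, 8), dtype=bool))
        part = road.voronoi_assign(region, np.array([[3.0, 2.0]]))
        assert (part.labels == 0).all()

    def test_two_generators_split_by_bisector(self):
        region = road.RoadRegion.from_mask(np.ones((4, 10), dtype=bool))
        part = road.voronoi_assign(region, np.array([[2.0, 1.5], [7.0, 1.5]]))
        for (x, _), lab in zip(part.pixels, part.labels):
            assert lab == (0 if x < 4.5 else 1)

    def test_tie_goes_to_lowest_index(self):
        region = road.RoadRegion.from_mask(np.ones((1, 3), dtype=bool))
        part = road.voronoi_assign(region, np.array([[0.0, 0.0], [2.0, 0.0]]))
        assert part.labels[1] == 0  # middle pixel equidistant

    def test_matches_brute_force_nearest_neighbor(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            region = random_blob_region(rng)
            n = int(rng.integers(2, 6))
            gens = region.pixels[rng.choice(region.n_pixels, n, replace=False)]
            part = road.voronoi_assign(region, gens)
            for pix, lab in zip(region.pixels, part.labels):
                dists = [np.linalg.norm(pix - g) for g in gens]
                assert lab == int(np.argmin(dists))

    def test_partition_covers_region_exactly(self):
        rng = np.random.default_rng(7)
        region = random_blob_region(rng)
        gens = region.pixels[rng.choice(region.n_pixels, 4, replace=False)]
        part = road.voronoi_assign(region, gens)
        assert sum((part.labels == i).sum() for i in range(4)) == region.n_pixels


class TestCentroidAndObjective:
    def test_uniform_rectangle_centroid_is_center(self):
        region = road.RoadRegion.from_mask(np.ones((5, 9), dtype=bool))
        part = road.voronoi_assign(region, np.array([[4.0, 2.0]]))
        np.testing.assert_allclose(road.cell_centroid(part, 0), [4.0, 2.0])

    def test_density_scale_invariance(self):
        region = road.RoadRegion.from_mask(np.ones((4, 6), dtype=bool))
        c1 = road.cell_centroid(
            road.voronoi_assign(region, [[2.0, 1.0]], density=lambda x, y: x + 1), 0
        )
        c2 = road.cell_centroid(
            road.voronoi_assign(
                region, [[2.0, 1.0]], density=lambda x, y: 2 * (x + 1)
            ),
            0,
        )
        np.testing.assert_allclose(c1, c2)

    def test_linear_density_on_strip_hand_computed(self):
        # strip x = 0..3, rho = x: centroid_x = sum(x^2)/sum(x) = 14/6
        region = road.RoadRegion.from_mask(np.ones((1, 4), dtype=bool))
        part = road.voronoi_assign(region, [[1.5, 0.0]], density=lambda x, y: x)
        np.testing.assert_allclose(road.cell_centroid(part, 0), [14 / 6, 0.0])

    def test_empty_cell_rejected(self):
        region = road.RoadRegion.from_mask(np.ones((2, 2), dtype=bool))
        part = road.voronoi_assign(region, [[0.0, 0.0], [100.0, 100.0]])
        with pytest.raises(ValueError):
            road.cell_centroid(part, 1)

    def test_objective_zero_when_generator_per_pixel(self):
        region = road.RoadRegion.from_mask(np.ones((2, 3), dtype=bool))
        part = road.voronoi_assign(region, region.pixels)
        assert road.objective(part) == 0.0

    def test_objective_three_pixel_line(self):
        region = road.RoadRegion.from_mask(np.ones((1, 3), dtype=bool))
        part = road.voronoi_assign(region, [[1.0, 0.0]])
        assert road.objective(part) == pytest.approx(2.0)


class TestLloyd:
    def test_single_generator_converges_to_region_centroid(self):
        region = road.RoadRegion.from_mask(np.ones((10, 10), dtype=bool))
        for seed in (0, 1):
            res = road.cvt_lloyd(region, road.CvtConfig(1, seed=seed, tol=1e-6))
            assert res.converged
            np.testing.assert_allclose(res.generators[0], [4.5, 4.5], atol=1e-6)

    def test_two_generators_on_2x1_rectangle_hit_half_centroids(self):
        """Best-of-restarts fixed point matches the direct computation:
        the optimal 2-cell CVT of a 20x10 rectangle splits it into two
        squares with centroids (4.5, 4.5) and (14.5, 4.5)."""
        region = road.RoadRegion.from_mask(np.ones((10, 20), dtype=bool))
        best = min(
            (
                road.cvt_lloyd(region, road.CvtConfig(2, seed=s, tol=1e-9))
                for s in range(5)
            ),
            key=lambda r: r.j_history[-1],
        )
        gens = best.generators[np.argsort(best.generators[:, 0])]
        np.testing.assert_allclose(gens, [[4.5, 4.5], [14.5, 4.5]], atol=1e-6)
        # J of the ideal split, computed directly
        xs, ys = np.meshgrid(np.arange(20.0), np.arange(10.0))
        left = (xs < 10)
        j_ideal = (
            ((xs - 4.5) ** 2 + (ys - 4.5) ** 2)[left].sum()
            + ((xs - 14.5) ** 2 + (ys - 4.5) ** 2)[~left].sum()
        )
        assert best.j_history[-1] == pytest.approx(j_ideal)

    def test_objective_non_increasing_and_fixed_point(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            region = random_blob_region(rng)
            n = int(rng.integers(2, 5))
            cfg = road.CvtConfig(n, seed=int(rng.integers(2**31)), tol=1e-3)
            res = road.cvt_lloyd(region, cfg)
            j = np.array(res.j_history)
            assert np.all(np.diff(j) <= 1e-8)
            if res.converged:
                for i in range(n):
                    if (res.partition.labels == i).any():
                        c = road.cell_centroid(res.partition, i)
                        assert np.linalg.norm(c - res.generators[i]) <= cfg.tol + 1e-9

    def test_too_many_generators_rejected(self):
        region = road.RoadRegion.from_mask(np.ones((2, 2), dtype=bool))
        with pytest.raises(ValueError):
            road.cvt_lloyd(region, road.CvtConfig(5))


class TestProjection:
    def test_bottom_edge_ground_distance(self):
        cam = road.CameraGeometry()
        # bottom image edge looks down pitch + vfov/2 = 60 degrees
        pt = road.pixel_to_robot((79.5, 119.5), cam)
        assert pt[0] == pytest.approx(0.65 / math.tan(math.radians(60.0)), abs=1e-9)
        assert pt[1] == pytest.approx(0.0, abs=1e-9)

    def test_image_center_ground_distance(self):
        cam = road.CameraGeometry()
        pt = road.pixel_to_robot((79.5, 59.5), cam)  # looks down 30 degrees
        assert pt[0] == pytest.approx(0.65 / math.tan(math.radians(30.0)), abs=1e-9)

    def test_round_trip_identity(self):
        cam = road.CameraGeometry()
        rng = np.random.default_rng(0)
        for _ in range(20):
            px = rng.uniform([0, 30], [159, 119])
            back = road.robot_to_pixel(road.pixel_to_robot(px, cam), cam)
            np.testing.assert_allclose(back, px, atol=1e-6)

    def test_horizon_ray_rejected(self):
        cam = road.CameraGeometry()
        with pytest.raises(ValueError):
            road.pixel_to_robot((80.0, -0.5), cam)  # exactly at the horizon

    def test_robot_to_world_identity_pose(self):
        pose = robot.RobotState(0.0, 0.0, 0.0)
        np.testing.assert_allclose(road.robot_to_world((1.2, -0.5), pose), [1.2, -0.5])

    def test_robot_to_world_quarter_turn(self):
        pose = robot.RobotState(1.0, 2.0, math.pi / 2)
        np.testing.assert_allclose(
            road.robot_to_world((3.0, 0.0), pose), [1.0, 5.0], atol=1e-12
        )

    def test_transform_composition(self):
        p1 = robot.RobotState(1.0, -1.0, 0.7)
        local = np.array([0.4, 0.2])
        via = road.robot_to_world(local, p1)
        back = road.world_to_robot(via, p1)
        np.testing.assert_allclose(back, local, atol=1e-12)


class TestSubgoalPipeline:
    def test_subgoals_inside_true_road_area(self, plain_scene):
        cfg, img, truth = plain_scene
        cam = road.CameraGeometry(image_size=(cfg.width, cfg.height))
        goals = road.generate_subgoals(
            img, cam, robot.RobotState(), road.CvtConfig(11, seed=1)
        )
        assert len(goals) == 11
        for g in goals:
            x, y = int(round(g.pixel[0])), int(round(g.pixel[1]))
            assert truth[y, x], f"sub-goal {g.number} at {g.pixel} off the road"

    def test_numbering_is_row_major_in_image(self, plain_scene):
        cfg, img, _ = plain_scene
        cam = road.CameraGeometry(image_size=(cfg.width, cfg.height))
        goals = road.generate_subgoals(
            img, cam, robot.RobotState(), road.CvtConfig(7, seed=2)
        )
        keys = [(g.pixel[1], g.pixel[0]) for g in goals]
        assert keys == sorted(keys)

    def test_single_subgoal_on_symmetry_axis(self):
        cfg = simulate.RoadSceneConfig()
        img, _ = simulate.generate_road_scene(cfg)
        cam = road.CameraGeometry(image_size=(cfg.width, cfg.height))
        goals = road.generate_subgoals(
            img, cam, robot.RobotState(), road.CvtConfig(1, seed=0, tol=1e-4)
        )
        assert goals[0].pixel[0] == pytest.approx((cfg.width - 1) / 2, abs=0.6)

    def test_fixed_seed_deterministic(self, plain_scene):
        cfg, img, _ = plain_scene
        cam = road.CameraGeometry(image_size=(cfg.width, cfg.height))
        g1 = road.generate_subgoals(img, cam, robot.RobotState(), road.CvtConfig(5, seed=3))
        g2 = road.generate_subgoals(img, cam, robot.RobotState(), road.CvtConfig(5, seed=3))
        assert [g.pixel for g in g1] == [g.pixel for g in g2]
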