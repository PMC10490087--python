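"""Point-cloud volume engine: back-projection, rules, integration, fallback."""

import numpy as np
import pytest

from conftest import small_camera
from mealvision import card, nutrition, scenes, volume
from mealvision.errors import EmptyAfterRules, EmptyItem, InsufficientPoints, MissingServing
from mealvision.geometry import DepthMap

RULES = volume.VolumeRules()


def flat_pose(depth_mm=400.0):
    return card.CardPose(np.array([0.0, 0.0, -1.0]),
                         np.array([0.0, 0.0, depth_mm]), depth_mm, np.eye(3))


def card_cloud(points):
    return volume.PointCloud(np.asarray(points, dtype=float), frame="card")


class TestBackproject:
    def test_principal_pixel_maps_to_axis(self):
        K = small_camera().K
        depth = DepthMap.from_array(np.full((240, 320), 400.0))
        mask = np.zeros((240, 320), bool)
        mask[120, 160] = True
        cloud = volume.backproject(depth, mask, K)
        assert np.allclose(cloud.points[0], [0.0, 0.0, 400.0])

    def test_one_pixel_off_axis(self):
        K = np.array([[800.0, 0, 320], [0, 800.0, 240], [0, 0, 1]])
        depth = DepthMap.from_array(np.full((480, 640), 400.0))
        mask = np.zeros((480, 640), bool)
        mask[240, 321] = True
        cloud = volume.backproject(depth, mask, K)
        assert cloud.points[0, 0] == pytest.approx(0.5)

    def test_cuboid_pixels_land_on_its_surface(self, cuboid_scene,
                                               cuboid_render):
        cam = cuboid_render.camera
        cloud = volume.backproject(cuboid_render.depth,
                                   cuboid_render.item_masks[0], cam.K)
        world = cam.camera_to_world(cloud.points)
        dist = cuboid_scene.solids[0].surface_distance(world)
        assert dist.max() < 0.5

    def test_empty_mask_raises(self):
        depth = DepthMap.from_array(np.full((24, 32), 400.0))
        with pytest.raises(EmptyItem):
            volume.backproject(depth, np.zeros((24, 32), bool),
                               small_camera().K)


class TestToCardFrame:
    def test_plane_points_map_to_zero_height(self, cuboid_render):
        det = card.detect_card(cuboid_render.intensity)
        pose = card.estimate_pose(det, card.CardSpec(),
                                  cuboid_render.camera.K)
        _, aligned = card.metric_align(cuboid_render.depth, pose,
                                       det.mask(cuboid_render.depth.shape))
        cloud = volume.backproject(aligned, cuboid_render.card_mask,
                                   cuboid_render.camera.K)
        cc = volume.to_card_frame(cloud, pose)
        assert np.abs(cc.points[:, 2]).max() < 0.5

    def test_rigidity_preserves_pairwise_distances(self):
        rng = np.random.default_rng(0)
        pts = rng.random((40, 3)) * 100
        cloud = volume.PointCloud(pts, frame="camera")
        out = volume.to_card_frame(cloud, flat_pose())
        d_in = np.linalg.norm(pts[:, None] - pts[None], axis=2)
        d_out = np.linalg.norm(out.points[:, None] - out.points[None], axis=2)
        assert np.abs(d_in - d_out).max() < 1e-6

    def test_cuboid_top_face_height(self, cuboid_render):
        det = card.detect_card(cuboid_render.intensity)
        pose = card.estimate_pose(det, card.CardSpec(),
                                  cuboid_render.camera.K)
        _, aligned = card.metric_align(cuboid_render.depth, pose,
                                       det.mask(cuboid_render.depth.shape))
        cloud = volume.backproject(aligned, cuboid_render.item_masks[0],
                                   cuboid_render.camera.K)
        cc = volume.to_card_frame(cloud, pose)
        top = cc.points[:, 2]
        assert np.median(top) == pytest.approx(30.0, abs=1.0)


class TestOutlierRemoval:
    def test_large_clean_grid_trims_only_the_boundary(self):
        # on a hard-edged clean grid the statistic flags only the outer
        # rings (a perimeter effect that vanishes as the cloud grows);
        # the interior must survive untouched
        n = 460
        xx, yy = np.meshgrid(np.arange(n) * 2.0, np.arange(n) * 2.0)
        pts = np.column_stack([xx.ravel(), yy.ravel(),
                               np.full(xx.size, 20.0)])
        cleaned, removed = volume.remove_statistical_outliers(card_cloud(pts))
        assert removed / len(pts) < 0.02
        kept = {tuple(p) for p in cleaned.points[:, :2]}
        gone = np.array(sorted(set(map(tuple, pts[:, :2])) - kept))
        border = np.minimum.reduce([gone[:, 0], gone[:, 1],
                                    2 * (n - 1) - gone[:, 0],
                                    2 * (n - 1) - gone[:, 1]])
        assert border.max() <= 4.0  # nothing beyond the outer two rings

    def test_far_point_removed_and_matches_direct_statistic(self):
        xx, yy = np.meshgrid(np.arange(40) * 2.0, np.arange(40) * 2.0)
        pts = np.column_stack([xx.ravel(), yy.ravel(), np.zeros(xx.size)])
        pts = np.vstack([pts, [[500.0, 500.0, 100.0]]])
        cleaned, removed = volume.remove_statistical_outliers(card_cloud(pts))
        assert removed >= 1
        assert not np.any(cleaned.points[:, 0] == 500.0)
        # direct oracle: the far point's mean 20-NN distance exceeds the
        # global mean + 2 sd computed straight from pairwise distances
        from scipy.spatial.distance import cdist
        d = cdist(pts, pts)
        knn = np.sort(d, axis=1)[:, 1:21].mean(axis=1)
        assert knn[-1] > knn.mean() + 2.0 * knn.std()

    def test_tiny_cloud_returned_unchanged(self):
        pts = np.random.default_rng(0).random((20, 3))
        cleaned, removed = volume.remove_statistical_outliers(card_cloud(pts),
                                                              k_neighbours=20)
        assert removed == 0
        assert np.array_equal(cleaned.points, pts)


class TestHeightRules:
    @pytest.mark.parametrize("z,kept", [
        (-10.0, False),   # implausibly below the card plane
        (70.0, False),    # above the 5 cm ceiling
        (25.0, True),     # inside the band
        (-3.0, True),     # small negative height: kept, clipped to 0
    ])
    def test_band_membership(self, z, kept):
        base = np.column_stack([np.arange(20.0), np.zeros(20),
                                np.full(20, 10.0)])
        probe = np.array([[0.0, 5.0, z]])
        out = volume.apply_height_rules(card_cloud(np.vstack([base, probe])),
                                        RULES)
        has_probe = np.any(np.isclose(out.points[:, 1], 5.0))
        assert has_probe == kept
        assert out.points[:, 2].min() >= 0.0
        assert out.points[:, 2].max() <= RULES.top_max_mm

    def test_all_points_outside_band_raises(self):
        pts = np.column_stack([np.arange(15.0), np.zeros(15),
                               np.full(15, 80.0)])
        with pytest.raises(EmptyAfterRules):
            volume.apply_height_rules(card_cloud(pts), RULES)


class TestIntegrateVolume:
    def test_dense_slab_integrates_to_analytic_volume(self):
        xx, yy = np.meshgrid(np.arange(0, 100, 0.5), np.arange(0, 80, 0.5))
        pts = np.column_stack([xx.ravel(), yy.ravel(),
                               np.full(xx.size, 30.0)])
        v = volume.integrate_volume(card_cloud(pts), RULES)
        assert v == pytest.approx(240.0, rel=0.02)

    def test_too_few_points_raises(self):
        pts = np.random.default_rng(0).random((9, 3))
        with pytest.raises(InsufficientPoints):
            volume.integrate_volume(card_cloud(pts), RULES)


class TestCapVolume:
    @pytest.mark.parametrize("v,expected,capped", [
        (750.0, 600.0, True),
        (100.0, 100.0, False),
        (600.0, 600.0, False),   # boundary: strict inequality
    ])
    def test_cap(self, v, expected, capped):
        out, flag = volume.cap_volume(v, RULES)
        assert out == expected and flag == capped


class TestEstimateItemVolume:
    @pytest.fixture(scope="class")
    def serving(self, primary_table):
        return primary_table

    def test_synthetic_scene_within_five_percent(self, cuboid_render,
                                                 serving):
        det = card.detect_card(cuboid_render.intensity)
        pose = card.estimate_pose(det, card.CardSpec(),
                                  cuboid_render.camera.K)
        _, aligned = card.metric_align(cuboid_render.depth, pose,
                                       det.mask(cuboid_render.depth.shape))
        est = volume.estimate_item_volume(
            aligned, cuboid_render.item_masks[0], pose, "beef steak",
            serving, RULES, intrinsics=cuboid_render.camera.K)
        assert est.card_found and not est.fallback_serving
        assert est.volume_mL == pytest.approx(240.0, rel=0.05)

    def test_missing_card_falls_back_to_serving(self, cuboid_render, serving):
        est = volume.estimate_item_volume(
            cuboid_render.depth, cuboid_render.item_masks[0], None,
            "beef steak", serving, RULES)
        assert est.fallback_serving and not est.card_found
        assert est.volume_mL == serving["beef steak"].serving_volume_mL

    def test_all_invalid_depth_falls_back(self, serving):
        depth = DepthMap(np.zeros((24, 32)), np.zeros((24, 32), bool))
        est = volume.estimate_item_volume(
            depth, np.ones((24, 32), bool), flat_pose(), "apple",
            serving, RULES, intrinsics=small_camera().K)
        assert est.fallback_serving

    def test_missing_serving_entry_is_an_error(self, serving):
        with pytest.raises(MissingServing):
            volume.estimate_item_volume(None, None, None, "unobtainium",
                                        serving, RULES)


class TestMetricInvariants:
    def scale_scene(self, c):
        spec = scenes.SceneSpec(
            card_centre_xy=(-95.3 * c, -69.6 * c),
            card_size_mm=(85.6 * c, 54.0 * c),
            solids=(scenes.SolidSpec(
                "cuboid", {"width": 100 * c, "depth": 80 * c,
                           "height": 30 * c}, (30.0 * c, 0.0), "beef steak"),),
            table_extent_mm=500.0 * c)
        return scenes.make_scene(spec)

    def run_pipeline(self, scene, cam, card_spec):
        out = scenes.render_depth(scene, cam)
        det = card.detect_card(out.intensity)
        pose = card.estimate_pose(det, card_spec, cam.K)
        card_mask = det.mask(out.depth.shape)
        _, aligned = card.metric_align(out.depth, pose, card_mask)
        pose = card.refine_pose_with_depth(aligned, card_mask, cam.K, pose)
        table = nutrition.load_nutrient_table(nutrition.bundled_table_path())
        return volume.estimate_item_volume(
            aligned, out.item_masks[0], pose, "beef steak", table, RULES,
            intrinsics=cam.K)

    def test_scene_scaling_scales_volume_cubically(self):
        """The card makes the system metric: scaling the world (card
        included) by c multiplies estimated volume by c^3."""
        c = 1.25
        base = self.run_pipeline(self.scale_scene(1.0), small_camera(),
                                 card.CardSpec(85.6, 54.0))
        scaled = self.run_pipeline(
            self.scale_scene(c), small_camera(distance=400.0 * c),
            card.CardSpec(85.6 * c, 54.0 * c))
        assert scaled.volume_mL == pytest.approx(base.volume_mL * c ** 3,
                                                 rel=0.01)

    def test_view_angle_robustness(self):
        """Estimates from 90 deg and 80 deg views differ < 10%."""
        scene = self.scale_scene(1.0)
        v90 = self.run_pipeline(scene, small_camera(90.0),
                                card.CardSpec()).volume_mL
        v80 = self.run_pipeline(scene, small_camera(80.0),
                                card.CardSpec()).volume_mL
        assert abs(v90 - v80) / v90 < 0.10

    def test_noise_degrades_gracefully(self):
        """2 mm Gaussian depth noise keeps cuboid volume error < 10%
        (median over seeds)."""
        scene = self.scale_scene(1.0)
        cam = small_camera()
        out = scenes.render_depth(scene, cam)
        det = card.detect_card(out.intensity)
        pose = card.estimate_pose(det, card.CardSpec(), cam.K)
        table = nutrition.load_nutrient_table(nutrition.bundled_table_path())
        errs = []
        for seed in range(5):
            noisy = scenes.add_depth_noise(out.depth, 2.0, 0.0, seed=seed)
            _, aligned = card.metric_align(noisy, pose,
                                           det.mask(out.depth.shape))
            est = volume.estimate_item_volume(
                aligned, out.item_masks[0], pose, "beef steak", table,
                RULES, intrinsics=cam.K)
            errs.append(abs(est.volume_mL - 240.0) / 240.0)
        assert np.median(errs) < 0.10
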