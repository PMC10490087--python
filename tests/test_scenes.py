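"""Renderer and scene-specification behaviour with analytic ground truth."""

import numpy as np
import pytest

from conftest import CUBOID_SPEC, small_camera, voxel_volume_mL
from mealvision import scenes
from mealvision.errors import CardOutOfView, SceneError
from mealvision.geometry import CameraModel


def solo_spec(kind, params, centre=(30.0, 0.0), category="apple"):
    return scenes.SceneSpec(solids=(
        scenes.SolidSpec(kind, params, centre, category),))


class TestClosedFormVolumes:
    def test_cuboid_volume_is_product_of_sides(self):
        scene = scenes.make_scene(solo_spec(
            "cuboid", {"width": 100, "depth": 80, "height": 30}))
        assert scene.analytic_volume_mL[0] == pytest.approx(240.0)

    def test_spherical_cap_closed_form(self):
        scene = scenes.make_scene(solo_spec(
            "spherical_cap", {"sphere_radius": 60, "height": 30}))
        assert scene.analytic_volume_mL[0] == pytest.approx(141.372, abs=1e-3)

    @pytest.mark.parametrize("kind,params", [
        ("cuboid", {"width": 100, "depth": 80, "height": 30}),
        ("cylinder", {"radius": 40, "height": 50}),
        ("spherical_cap", {"sphere_radius": 60, "height": 30}),
        ("frustum", {"radius_bottom": 45, "radius_top": 30, "height": 30}),
    ])
    def test_closed_form_matches_voxel_oracle(self, kind, params):
        scene = scenes.make_scene(solo_spec(kind, params))
        oracle = voxel_volume_mL(kind, params, step=0.25)
        assert scene.analytic_volume_mL[0] == pytest.approx(oracle, rel=1e-3)

    @pytest.mark.parametrize("kind,params", [
        ("cylinder", {"radius": 40, "height": 0}),
        ("cuboid", {"width": -5, "depth": 80, "height": 30}),
        ("spherical_cap", {"sphere_radius": 20, "height": 45}),
        ("frustum", {"radius_bottom": 0, "radius_top": 30, "height": 30}),
    ])
    def test_degenerate_shape_parameters_rejected(self, kind, params):
        with pytest.raises(SceneError):
            scenes.make_scene(solo_spec(kind, params))

    def test_solid_overlapping_card_rejected(self):
        spec = solo_spec("cylinder", {"radius": 40, "height": 30},
                         centre=(-95.0, -70.0))
        with pytest.raises(SceneError, match="overlaps the card"):
            scenes.make_scene(spec)


class TestRenderDepth:
    def test_empty_table_has_constant_depth(self, empty_scene):
        out = scenes.render_depth(empty_scene, small_camera())
        vals = out.depth.values[out.depth.valid]
        assert np.allclose(vals[np.abs(vals - 400) < 1], 400.0)
        # fronto-parallel plane: centre pixel exactly at the standoff
        assert out.depth.values[120, 160] == pytest.approx(400.0)

    def test_cuboid_top_face_depth(self, cuboid_render):
        mask = cuboid_render.item_masks[0]
        top = np.abs(cuboid_render.depth.values[mask] - 370.0) < 1e-6
        assert top.mean() > 0.95  # nearly all mask pixels on the top face

    def test_card_projected_width_follows_pinhole(self, empty_scene):
        cam = CameraModel.overhead_arc(np.zeros(3), 400.0, 90.0,
                                       fx=800.0, width=640, height=480)
        out = scenes.render_depth(empty_scene, cam)
        widths = np.abs(out.card_corners_px[1] - out.card_corners_px[0])
        assert widths[0] == pytest.approx(85.6 * 800 / 400)  # = 171.2 px

    def test_card_corners_are_exact_projections(self, cuboid_scene,
                                                cuboid_render):
        cam = cuboid_render.camera
        expected = cam.project(cuboid_scene.card_corner_world)
        assert np.allclose(cuboid_render.card_corners_px, expected)

    def test_item_masks_pairwise_disjoint(self):
        spec = scenes.SceneSpec(solids=(
            scenes.SolidSpec("cuboid", {"width": 60, "depth": 50, "height": 20},
                             (0.0, 40.0), "white bread"),
            scenes.SolidSpec("cylinder", {"radius": 30, "height": 40},
                             (50.0, -50.0), "orange juice"),
        ))
        out = scenes.render_depth(scenes.make_scene(spec), small_camera())
        assert not np.any(out.item_masks[0] & out.item_masks[1])

    def test_card_outside_frustum_is_an_error(self, cuboid_scene):
        narrow = CameraModel.overhead_arc(np.zeros(3), 400.0, 90.0,
                                          fx=3000.0, width=320, height=240)
        with pytest.raises(CardOutOfView):
            scenes.render_depth(cuboid_scene, narrow)

    def test_backprojected_pixels_lie_on_scene_surfaces(self, cuboid_scene,
                                                        cuboid_render):
        """Renderer self-consistency: every valid pixel back-projects onto
        the table plane or a solid surface to < 0.5 mm."""
        cam = cuboid_render.camera
        origin, dirs = cam.pixel_rays()
        d = cuboid_render.depth
        pts = origin + d.values[..., None] * dirs
        pts = pts[d.valid]
        dist = np.abs(pts[:, 2])  # distance to the table plane
        for solid in cuboid_scene.solids:
            dist = np.minimum(dist, solid.surface_distance(pts))
        assert dist.max() < 0.5


class TestStereoRender:
    def test_identical_cameras_give_zero_disparity(self, cuboid_scene):
        cam = small_camera()
        _, _, corr = scenes.render_stereo(cuboid_scene, cam, cam)
        assert np.allclose(corr.uv_a, corr.uv_b)

    def test_horizontal_baseline_disparity_is_fb_over_z(self):
        scene = scenes.make_scene(scenes.SceneSpec(card_centre_xy=(0.0, -70.0)))
        cam_a = CameraModel.looking_at([0, 0, 400], [0, 0, 0], fx=800.0,
                                       width=640, height=480)
        cam_b = CameraModel.looking_at([60, 0, 400], [60, 0, 0], fx=800.0,
                                       width=640, height=480)
        _, _, corr = scenes.render_stereo(scene, cam_a, cam_b)
        disp = corr.uv_a[:, 0] - corr.uv_b[:, 0]
        assert np.allclose(disp, 800 * 60 / 400)  # 120 px at every point
        assert np.allclose(corr.uv_a[:, 1], corr.uv_b[:, 1])

    def test_default_second_view_sits_at_75_degrees(self, cuboid_scene):
        _, out_b, _ = scenes.render_stereo(cuboid_scene, small_camera())
        assert out_b.camera.elevation_deg == pytest.approx(75.0, abs=0.1)
        assert np.linalg.norm(out_b.camera.centre_world) == pytest.approx(400.0)


class TestDepthNoise:
    def test_zero_noise_is_bit_identical(self, cuboid_render):
        out = scenes.add_depth_noise(cuboid_render.depth, 0.0, 0.0, seed=1)
        assert np.array_equal(out.values, cuboid_render.depth.values)
        assert np.array_equal(out.valid, cuboid_render.depth.valid)

    def test_same_seed_reproduces_bits(self, cuboid_render):
        a = scenes.add_depth_noise(cuboid_render.depth, 2.0, 0.02, seed=7)
        b = scenes.add_depth_noise(cuboid_render.depth, 2.0, 0.02, seed=7)
        assert np.array_equal(a.values, b.values)

    def test_outlier_count_is_rounded_fraction(self):
        from mealvision.geometry import DepthMap
        depth = DepthMap.from_array(np.full((100, 100), 400.0))
        noisy = scenes.add_depth_noise(depth, 0.0, 0.05, seed=3)
        assert int((noisy.values != 400.0).sum()) == 500

    def test_invalid_fraction_rejected(self, cuboid_render):
        with pytest.raises(ValueError):
            scenes.add_depth_noise(cuboid_render.depth, 1.0, 1.0, seed=0)


class TestGenerateStudy:
    def test_noiseless_reference_equals_truth(self):
        study = scenes.generate_study(4, noise_cv=0.0, seed=5)
        for p in study.participants:
            ref = study.reference_daily[p.participant_id]
            for k, v in p.true_daily.items():
                assert ref[k] == v

    def test_same_seed_is_identical(self):
        a = scenes.generate_study(6, noise_cv=0.1, seed=11)
        b = scenes.generate_study(6, noise_cv=0.1, seed=11)
        assert a.reference_daily == b.reference_daily
        assert [p.true_daily for p in a.participants] == \
               [p.true_daily for p in b.participants]

    def test_empirical_cv_matches_configured_noise(self):
        study = scenes.generate_study(200, noise_cv=0.10, seed=2)
        ratios = np.array([
            study.reference_daily[p.participant_id]["kcal"]
            / p.true_daily["kcal"] for p in study.participants
        ])
        cv = ratios.std() / ratios.mean()
        assert 0.08 <= cv <= 0.12

    def test_empty_catalogue_is_an_error(self):
        with pytest.raises(ValueError, match="catalogue"):
            scenes.generate_study(2, catalogue=[], seed=0)
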