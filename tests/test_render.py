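"""Camera trajectories and ray-cast Phong rendering."""

import numpy as np
import pytest

from uroscope import (CameraPose, LightingConfig, PRESETS, Skeleton,
                      TriangleMesh, render, sample_trajectory)


def wall_mesh(distance: float = 100.0, half: float = 2000.0) -> TriangleMesh:
    verts = np.array([[distance, -half, -half], [distance, -half, half],
                      [distance, half, half], [distance, half, -half]])
    return TriangleMesh(verts, np.array([[0, 1, 2], [0, 2, 3]]))


def line_skeleton(p0, p1) -> Skeleton:
    return Skeleton(np.array([p0, p1], dtype=float), np.array([[0, 1]]),
                    np.array([1, 1]))


class TestTrajectory:
    def test_even_spacing_inclusive_of_endpoints(self):
        skel = line_skeleton([0, 0, 0], [10, 0, 0])
        poses = sample_trajectory(skel, 2.0)
        assert len(poses) == 6
        xs = [p.position[0] for p in poses]
        np.testing.assert_allclose(xs, [0, 2, 4, 6, 8, 10], atol=1e-12)

    def test_positions_lie_on_skeleton_segments(self):
        skel = Skeleton(np.array([[0.0, 0, 0], [5, 0, 0], [5, 7, 0]]),
                        np.array([[0, 1], [1, 2]]), np.array([1, 1, 1]))
        for pose in sample_trajectory(skel, 1.5):
            p = pose.position
            d = min(np.linalg.norm(p - np.clip(p[0], 0, 5) * np.array([1.0, 0, 0])),
                    np.linalg.norm(p - (np.array([5.0, 0, 0])
                                        + np.clip(p[1], 0, 7) * np.array([0.0, 1, 0]))))
            assert d <= 1e-9

    def test_straight_line_has_constant_view_direction(self):
        poses = sample_trajectory(line_skeleton([0, 0, 0], [10, 0, 0]), 2.5)
        dirs = np.array([p.view_dir for p in poses])
        assert np.allclose(dirs, dirs[0])

    def test_up_vectors_stay_orthonormal_through_a_bend(self):
        skel = Skeleton(np.array([[0.0, 0, 0], [10, 0, 0], [10, 10, 0]]),
                        np.array([[0, 1], [1, 2]]), np.array([1, 1, 1]))
        for pose in sample_trajectory(skel, 2.0):
            assert abs(pose.view_dir @ pose.up) < 1e-9
            assert np.linalg.norm(pose.up) == pytest.approx(1.0)

    def test_empty_skeleton_rejected(self):
        empty = Skeleton(np.zeros((1, 3)), np.zeros((0, 2), dtype=int), np.array([1]))
        with pytest.raises(ValueError, match="edges"):
            sample_trajectory(empty, 1.0)


class TestRenderShading:
    def test_ambient_only_is_uniform_and_view_independent(self):
        pose = CameraPose(np.zeros(3), [1, 0, 0], [0, 0, 1], vfov_deg=60)
        cfg = LightingConfig(ambient=1.0, diffuse=0.0, specular=0.0,
                             base_color=(0.6, 0.6, 0.6))
        img = render(wall_mesh(), pose, cfg, (33, 33))
        hit = img.sum(axis=2) > 0
        assert hit.all()
        assert np.unique(img[hit]).tolist() == [pytest.approx(0.6)]

    def test_headlight_diffuse_follows_lambert_cosine(self):
        # wall far enough that the 1 mm headlight offset is negligible:
        # brightness at 60 deg incidence is half the head-on brightness
        pose = CameraPose(np.zeros(3), [1, 0, 0], [0, 0, 1], vfov_deg=140)
        cfg = LightingConfig(ambient=0, diffuse=1.0, specular=0, headlight=True)
        h = 129
        img = render(wall_mesh(distance=100.0), pose, cfg, (h, h))
        lum = img.mean(axis=2)
        tan_half = np.tan(np.deg2rad(70))
        ys = (1.0 - 2.0 * (np.arange(h) + 0.5) / h) * tan_half
        row60 = int(np.argmin(np.abs(np.degrees(np.arctan(np.abs(ys))) - 60.0)))
        ratio = lum[row60, h // 2] / lum[h // 2, h // 2]
        assert ratio == pytest.approx(0.5, rel=0.02)

    def test_doubling_diffuse_doubles_surface_brightness(self, cylinder_mesh):
        pose = CameraPose([10.0, 0, 0], [1, 0, 0], [0, 0, 1])
        lo = render(cylinder_mesh, pose,
                    LightingConfig(ambient=0, diffuse=0.2, specular=0, headlight=True),
                    (48, 48))
        hi = render(cylinder_mesh, pose,
                    LightingConfig(ambient=0, diffuse=0.4, specular=0, headlight=True),
                    (48, 48))
        np.testing.assert_allclose(hi, 2 * lo, atol=1e-12)

    def test_render_is_deterministic(self, cylinder_mesh):
        pose = CameraPose([10.0, 0, 0], [1, 0, 0], [0, 0, 1])
        a = render(cylinder_mesh, pose, PRESETS["customlight"], (48, 48))
        b = render(cylinder_mesh, pose, PRESETS["customlight"], (48, 48))
        np.testing.assert_array_equal(a, b)

    def test_interior_tube_view_has_no_central_background(self, cylinder_mesh):
        pose = CameraPose([10.0, 0, 0], [1, 0, 0], [0, 0, 1])
        img = render(cylinder_mesh, pose, PRESETS["customlight"], (96, 96))
        central = img[32:64, 32:64]
        assert np.all(central.sum(axis=2) > 0)

    def test_distance_falloff_darkens_far_wall(self):
        pose = CameraPose(np.zeros(3), [1, 0, 0], [0, 0, 1])
        cfg = LightingConfig(ambient=0, diffuse=1.0, specular=0, headlight=True,
                             distance_falloff=True)
        near = render(wall_mesh(distance=10.0), pose, cfg, (17, 17))
        far = render(wall_mesh(distance=20.0), pose, cfg, (17, 17))
        assert far[8, 8].mean() < near[8, 8].mean()

    def test_wireframe_overlay_uses_palette_colors(self, cylinder_mesh):
        pose = CameraPose([10.0, 0, 0], [1, 0, 0], [0, 0, 1])
        img = render(cylinder_mesh, pose, PRESETS["baseline"], (64, 64))
        palette = np.asarray(PRESETS["baseline"].edge_palette)
        flat = img.reshape(-1, 3)
        found = sum(np.any(np.all(np.isclose(flat, c, atol=1e-9), axis=1))
                    for c in palette)
        assert found >= 2  # several distinct edge colors visible

    def test_zero_resolution_rejected(self, cylinder_mesh):
        pose = CameraPose([10.0, 0, 0], [1, 0, 0], [0, 0, 1])
        with pytest.raises(ValueError, match="resolution"):
            render(cylinder_mesh, pose, PRESETS["customlight"], (0, 16))

    def test_pose_validation(self):
        with pytest.raises(ValueError, match="orthogonal"):
            CameraPose(np.zeros(3), [1, 0, 0], [1, 0, 0])
        with pytest.raises(ValueError, match="fractions|\\[0, 1\\]"):
            LightingConfig(ambient=1.5)
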