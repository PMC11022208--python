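"""Wave propagation, ring contraction, multi-wave averaging and the
surface-coverage statistic."""

import numpy as np
import pytest
import trimesh

from uroscope import (Skeleton, TriangleMesh, WaveParams, contract_to_skeleton,
                      coverage_distance, propagate_wave, skeletonize)

from conftest import build_cylinder_mesh
from oracles import bfs_steps, mean_min_segment_distance


def strip_mesh(n_tri: int = 12) -> TriangleMesh:
    """A flat triangle strip: the edge graph is a ladder (path-like)."""
    verts = [[0.0, 0, 0], [0.0, 1, 0]]
    faces = []
    for i in range(n_tri):
        verts.append([float(i + 1), (i + 1) % 2, 0.0])
        faces.append([i, i + 1, i + 2])
    return TriangleMesh(np.asarray(verts), np.asarray(faces))


class TestPropagateWave:
    def test_matches_plain_bfs_on_strip(self):
        mesh = strip_mesh(14)
        steps = propagate_wave(mesh, 0)
        ref = bfs_steps(mesh.n_vertices, mesh.edges_unique(), 0)
        np.testing.assert_array_equal(steps, ref)
        assert steps[0] == 0

    def test_matches_plain_bfs_on_tube(self, y_mesh):
        steps = propagate_wave(y_mesh, 3)
        ref = bfs_steps(y_mesh.n_vertices, y_mesh.edges_unique(), 3)
        np.testing.assert_array_equal(steps, ref)

    def test_step_difference_at_most_one_across_edges(self, y_mesh):
        steps = propagate_wave(y_mesh, 0)
        e = y_mesh.edges_unique()
        assert np.all(np.abs(steps[e[:, 0]] - steps[e[:, 1]]) <= 1)

    def test_disconnected_component_flagged_unreached(self):
        a = strip_mesh(4)
        b = strip_mesh(4)
        verts = np.vstack([a.vertices, b.vertices + [0, 0, 10]])
        faces = np.vstack([a.faces, b.faces + a.n_vertices])
        mesh = TriangleMesh(verts, faces)
        steps = propagate_wave(mesh, 0)
        assert np.all(steps[:a.n_vertices] >= 0)
        assert np.all(steps[a.n_vertices:] == -1)

    def test_out_of_range_source_rejected(self):
        with pytest.raises(IndexError):
            propagate_wave(strip_mesh(3), 99)

    def test_geodesic_metric_orders_like_distance(self, cylinder_mesh):
        steps = propagate_wave(cylinder_mesh, 0, geodesic=True)
        assert steps.min() == 0 and steps.max() > 0


class TestContract:
    def test_cylinder_nodes_lie_on_axis(self, cylinder_mesh):
        cap_center = cylinder_mesh.n_vertices - 2  # on-axis cap vertex
        steps = propagate_wave(cylinder_mesh, cap_center)
        skel = contract_to_skeleton(cylinder_mesh, steps, 5)
        axis_dist = np.linalg.norm(skel.nodes[:, 1:], axis=1)
        assert axis_dist.max() <= 0.1 * 5.0

    def test_node_count_non_increasing_in_step_size(self, cylinder_mesh, y_mesh):
        for mesh in (cylinder_mesh, y_mesh):
            steps = propagate_wave(mesh, 0)
            counts = [contract_to_skeleton(mesh, steps, s).n_nodes
                      for s in (1, 2, 5, 10)]
            assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_y_tube_has_exactly_one_bifurcation_node(self, y_mesh):
        skel = skeletonize(y_mesh, WaveParams(step_size=5, wave_count=1))
        deg = skel.degrees()
        assert int((deg == 3).sum()) == 1
        assert int((deg == 1).sum()) == 3

    def test_empty_mesh_rejected(self):
        mesh = TriangleMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=int))
        with pytest.raises(ValueError, match="empty"):
            contract_to_skeleton(mesh, np.zeros(0, dtype=int), 5)


class TestSkeletonize:
    def test_single_wave_reduces_to_contraction(self, cylinder_mesh):
        skel = skeletonize(cylinder_mesh, WaveParams(step_size=5, wave_count=1))
        seed = skel.meta["seeds"][0]
        ref = contract_to_skeleton(cylinder_mesh, propagate_wave(cylinder_mesh, seed), 5)
        np.testing.assert_array_equal(skel.nodes, ref.nodes)
        np.testing.assert_array_equal(skel.edges, ref.edges)

    def test_second_wave_does_not_decenter_cylinder(self, cylinder_mesh):
        d = {}
        for wc in (1, 2):
            skel = skeletonize(cylinder_mesh, WaveParams(step_size=5, wave_count=wc))
            d[wc] = np.linalg.norm(skel.nodes[:, 1:], axis=1).mean()
        assert d[2] <= d[1] + 1e-9

    def test_deterministic_under_seed(self, y_mesh):
        s1 = skeletonize(y_mesh, WaveParams(step_size=5, wave_count=2, rng_seed=3))
        s2 = skeletonize(y_mesh, WaveParams(step_size=5, wave_count=2, rng_seed=3))
        np.testing.assert_array_equal(s1.nodes, s2.nodes)
        np.testing.assert_array_equal(s1.edges, s2.edges)

    def test_nodes_of_tube_lie_strictly_inside_mesh(self, cylinder_mesh):
        # analytic containment for the cylinder: axis distance < radius and
        # axial coordinate within the caps
        skel = skeletonize(cylinder_mesh, WaveParams(step_size=5, wave_count=2))
        axis_dist = np.linalg.norm(skel.nodes[:, 1:], axis=1)
        assert np.all(axis_dist < 5.0)
        assert np.all((skel.nodes[:, 0] >= 0.0) & (skel.nodes[:, 0] <= 60.0))

    def test_too_many_waves_rejected(self):
        mesh = strip_mesh(3)
        with pytest.raises(ValueError):
            skeletonize(mesh, WaveParams(step_size=1, wave_count=mesh.n_vertices + 1))

    def test_json_roundtrip(self, tmp_path, y_mesh):
        skel = skeletonize(y_mesh, WaveParams())
        skel.to_json(tmp_path / "s.json")
        back = Skeleton.from_json(tmp_path / "s.json")
        np.testing.assert_allclose(back.nodes, skel.nodes)
        np.testing.assert_array_equal(back.edges, skel.edges)
        assert back.meta["step_size"] == 5


class TestCoverage:
    def test_sphere_with_center_node_returns_radius(self, sphere_mesh):
        center = sphere_mesh.vertices.mean(axis=0)
        skel = Skeleton(center[None, :], np.zeros((0, 2), dtype=int), np.array([1]))
        d = coverage_distance(sphere_mesh, skel, n_samples=5000, rng_seed=0)
        assert d == pytest.approx(10.0, rel=0.02)

    def test_skeleton_on_every_sample_gives_zero(self, y_mesh):
        tm = trimesh.Trimesh(y_mesh.vertices, y_mesh.faces, process=False)
        pts, _ = trimesh.sample.sample_surface(tm, 64, seed=11)
        skel = Skeleton(np.asarray(pts), np.zeros((0, 2), dtype=int),
                        np.ones(len(pts), dtype=int))
        assert coverage_distance(y_mesh, skel, n_samples=64, rng_seed=11) == \
            pytest.approx(0.0, abs=1e-9)

    def test_matches_brute_force_double_loop(self, y_mesh):
        skel = skeletonize(y_mesh, WaveParams(step_size=5, wave_count=1))
        fast = coverage_distance(y_mesh, skel, n_samples=200, rng_seed=5)
        tm = trimesh.Trimesh(y_mesh.vertices, y_mesh.faces, process=False)
        pts, _ = trimesh.sample.sample_surface(tm, 200, seed=5)
        ref = mean_min_segment_distance(np.asarray(pts),
                                        skel.nodes[skel.edges[:, 0]],
                                        skel.nodes[skel.edges[:, 1]])
        assert fast == pytest.approx(ref, rel=1e-12)

    def test_empty_skeleton_rejected(self, y_mesh):
        empty = Skeleton(np.zeros((0, 3)), np.zeros((0, 2), dtype=int),
                         np.zeros(0, dtype=int))
        with pytest.raises(ValueError, match="empty"):
            coverage_distance(y_mesh, empty)
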