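"""Shared geometry fixtures: analytic tubes, voxel phantoms, label maps."""

from __future__ import annotations

import numpy as np
import pytest

from uroscope import LabelMap, TriangleMesh, marching_cubes, smooth_binary
from uroscope.phantom import _paint_capsule, make_cylinder_mesh

build_cylinder_mesh = make_cylinder_mesh


@pytest.fixture(scope="session")
def cylinder_mesh() -> TriangleMesh:
    return build_cylinder_mesh()


@pytest.fixture(scope="session")
def y_mesh() -> TriangleMesh:
    """Y-shaped closed tube: one stem splitting into two branches."""
    mask = np.zeros((80, 64, 64), dtype=bool)
    sp = np.ones(3)
    _paint_capsule(mask, sp, np.array([8.0, 32, 32]), np.array([40.0, 32, 32]), 5.0)
    _paint_capsule(mask, sp, np.array([40.0, 32, 32]), np.array([68.0, 18, 32]), 4.0)
    _paint_capsule(mask, sp, np.array([40.0, 32, 32]), np.array([68.0, 46, 32]), 4.0)
    lm = LabelMap(mask.astype(np.uint8), tuple(sp),
                  label_semantics={0: "background", 1: "kidney"})
    return marching_cubes(smooth_binary(lm, 0.8), 0.5)


@pytest.fixture(scope="session")
def sphere_label() -> LabelMap:
    """Solid voxel sphere, radius 10 vox, in a 32^3 grid at 1 mm spacing."""
    n, r = 32, 10.0
    zz, yy, xx = np.mgrid[0:n, 0:n, 0:n]
    c = (n - 1) / 2
    mask = ((zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2) <= r ** 2
    return LabelMap(mask.astype(np.uint8), (1.0, 1.0, 1.0),
                    label_semantics={0: "background", 1: "kidney"})


@pytest.fixture(scope="session")
def sphere_mesh(sphere_label) -> TriangleMesh:
    return marching_cubes(smooth_binary(sphere_label, 0.8), 0.5)
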