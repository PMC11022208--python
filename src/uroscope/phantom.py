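"""Synthetic kidney phantoms and endoscopy-style image domains.

A phantom emulates delayed-phase contrast CT of one kidney: a bright
branching cavity (renal pelvis plus calyces, where contrast pools) wrapped
in a mid-intensity parenchyma shell on a dark background, with Gaussian
noise.  Ground truth — the three-class label map and the branching
centerline — is known by construction, so extraction, meshing,
skeletonization and rendering can all be validated without any clinical
data.

Geometry: a pelvis ellipsoid at the kidney centre, ``n_calyces`` capsule
branches fanned over the upper hemisphere at evenly spaced azimuths (with
seeded jitter), and one entry tube (ureter direction) leaving downward.
Default intensities (-100 / 80 / 300 HU, noise sd 20) give the three
well-separated modes that delayed-phase contrast produces; they are
plausible HU magnitudes, configurable, and not fitted to any dataset.

``make_style_domain`` maps grayscale renders to a pinkish tissue palette
with low-frequency mottling, a vignette, and specular highlights — a
reachable stand-in target domain for the style-transfer smoke harness
(real ureteroscopy frames are not publicly available).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .volumes import LabelMap, Volume

__all__ = ["PhantomSpec", "PhantomTruth", "make_phantom", "make_style_domain",
           "make_cylinder_mesh"]


def make_cylinder_mesh(radius: float = 5.0, length: float = 60.0,
                       n_theta: int = 16, n_len: int = 31):
    """Analytic closed cylinder mesh along the first axis with fan caps.

    The cap centre vertices lie exactly on the axis, so ring contraction has
    on-axis terminal nodes; useful as a known-geometry skeletonization
    fixture (every ring centroid lies on the axis by symmetry).
    """
    from .meshing import TriangleMesh

    zs = np.linspace(0.0, length, n_len)
    th = np.arange(n_theta) / n_theta * 2 * np.pi
    verts = [[z, radius * np.cos(t), radius * np.sin(t)] for z in zs for t in th]
    faces = []

    def vid(i, j):
        return i * n_theta + (j % n_theta)

    for i in range(n_len - 1):
        for j in range(n_theta):
            a, b, c, d = vid(i, j), vid(i, j + 1), vid(i + 1, j), vid(i + 1, j + 1)
            faces += [[a, b, d], [a, d, c]]
    c0 = len(verts)
    verts.append([0.0, 0.0, 0.0])
    c1 = len(verts)
    verts.append([length, 0.0, 0.0])
    for j in range(n_theta):
        faces.append([c0, vid(0, j + 1), vid(0, j)])
        faces.append([c1, vid(n_len - 1, j), vid(n_len - 1, j + 1)])
    return TriangleMesh(np.asarray(verts, dtype=float), np.asarray(faces))


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic kidney phantom (all lengths in mm)."""

    grid_shape: tuple[int, int, int] = (96, 96, 96)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    pelvis_semi_axes: tuple[float, float, float] = (10.0, 12.0, 9.0)
    n_calyces: int = 6
    branch_length_range: tuple[float, float] = (12.0, 24.0)
    branch_radius_range: tuple[float, float] = (2.5, 4.0)
    entry_radius: float = 3.0
    shell_thickness: float = 4.0
    intensities: tuple[float, float, float] = (-100.0, 80.0, 300.0)  # bg, parenchyma, contrast
    noise_sd: float = 20.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        bg, par, con = self.intensities
        if not (con > par > bg):
            raise ValueError("intensities must satisfy contrast > parenchyma > background")
        if self.branch_radius_range[0] <= max(self.spacing):
            raise ValueError("branch radii must exceed the voxel spacing")
        if not (1 <= self.n_calyces <= 12):
            raise ValueError("n_calyces must be in [1, 12]")


@dataclasses.dataclass
class PhantomTruth:
    """A phantom CT with its ground-truth labels and centerline tree."""

    ct: Volume
    labels: LabelMap
    centerline: list[np.ndarray]  # polylines in mm, (z, y, x) order
    spec: PhantomSpec

    def centerline_points(self) -> np.ndarray:
        return np.vstack(self.centerline)


def _paint_capsule(mask: np.ndarray, spacing: np.ndarray, a: np.ndarray,
                   b: np.ndarray, radius: float) -> None:
    """Mark voxels within ``radius`` mm of segment [a, b] (coords in mm)."""
    lo = np.maximum(np.floor((np.minimum(a, b) - radius) / spacing).astype(int) - 1, 0)
    hi = np.minimum(np.ceil((np.maximum(a, b) + radius) / spacing).astype(int) + 2,
                    np.asarray(mask.shape))
    if (lo >= hi).any():
        return
    grids = np.meshgrid(*[(np.arange(l, h) + 0.5) * s for l, h, s in zip(lo, hi, spacing)],
                        indexing="ij")
    p = np.stack(grids, axis=-1)
    ab = b - a
    ab2 = float(ab @ ab)
    if ab2 == 0:
        d = np.linalg.norm(p - a, axis=-1)
    else:
        t = np.clip(((p - a) @ ab) / ab2, 0.0, 1.0)
        d = np.linalg.norm(p - (a + t[..., None] * ab), axis=-1)
    sub = tuple(slice(l, h) for l, h in zip(lo, hi))
    mask[sub] |= d <= radius


def make_phantom(spec: PhantomSpec = PhantomSpec()) -> PhantomTruth:
    """Build a phantom kidney; deterministic under ``spec.rng_seed``."""
    rng = np.random.default_rng(spec.rng_seed)
    shape = np.asarray(spec.grid_shape)
    spacing = np.asarray(spec.spacing, dtype=float)
    extent = shape * spacing
    margin = 3.0 + max(spec.branch_radius_range)
    center = np.array([0.45 * extent[0], 0.5 * extent[1], 0.5 * extent[2]])

    collecting = np.zeros(tuple(shape), dtype=bool)
    # pelvis ellipsoid
    grids = np.meshgrid(*[(np.arange(n) + 0.5) * s for n, s in zip(shape, spacing)],
                        indexing="ij")
    p = np.stack(grids, axis=-1)
    axes = np.asarray(spec.pelvis_semi_axes)
    collecting |= (((p - center) / axes) ** 2).sum(axis=-1) <= 1.0

    centerline: list[np.ndarray] = []
    # entry funnel: the pelvis tapers smoothly into the ureter direction
    # (a thin tube T-joined to a wide chamber would leave a pocket where a
    # surface wave terminates; the real pelvis is funnel-shaped)
    entry_end = np.array([margin + spec.entry_radius, center[1], center[2]])
    funnel_r0 = float(min(axes))  # mouth as wide as the pelvis: no shelf annulus
    taper_end = center + 0.6 * (entry_end - center)
    n_taper = 8
    for i in range(n_taper):
        t0, t1 = i / n_taper, (i + 1) / n_taper
        a = center + t0 * (taper_end - center)
        b = center + t1 * (taper_end - center)
        r = funnel_r0 + (spec.entry_radius - funnel_r0) * t1
        _paint_capsule(collecting, spacing, a, b, r)
    _paint_capsule(collecting, spacing, taper_end, entry_end, spec.entry_radius)
    centerline.append(np.stack([center, taper_end, entry_end]))

    # calyces: evenly spaced azimuths with jitter, polar angles toward +z
    # staggered between an upper and a lower cone.  The stagger keeps
    # neighbouring branches disjoint in 3D angle and their openings on the
    # upper pelvis, clear of the entry funnel — otherwise the ground-truth
    # branch count would not describe the cavity's actual topology.
    for k in range(spec.n_calyces):
        phi = 2 * np.pi * k / spec.n_calyces + rng.uniform(-0.12, 0.12)
        theta_base = 33.0 if k % 2 == 0 else 49.0
        theta = np.deg2rad(theta_base + rng.uniform(-4.0, 4.0))
        direction = np.array([np.cos(theta),
                              np.sin(theta) * np.cos(phi),
                              np.sin(theta) * np.sin(phi)])
        radius = rng.uniform(*spec.branch_radius_range)
        length = rng.uniform(*spec.branch_length_range)
        # start just inside the pelvis surface so the branch is connected
        surf_r = 1.0 / np.sqrt((((direction) / axes) ** 2).sum())
        start = center + 0.8 * surf_r * direction
        # shrink length until the capsule fits inside the grid margin
        lo_lim = np.full(3, margin)
        hi_lim = extent - margin
        end = start + length * direction
        while length > 0 and ((end - radius < lo_lim) | (end + radius > hi_lim)).any():
            length -= 1.0
            end = start + length * direction
        if length < spec.branch_length_range[0] * 0.5:
            raise ValueError(f"calyx branch {k} does not fit inside the grid; "
                             "enlarge grid_shape or shorten branch_length_range")
        _paint_capsule(collecting, spacing, start, end, radius)
        centerline.append(np.stack([center, start, end]))

    # parenchyma shell: everything within shell_thickness of the cavity
    dt = ndimage.distance_transform_edt(~collecting, sampling=spacing)
    kidney_region = dt <= spec.shell_thickness
    labels = np.zeros(tuple(shape), dtype=np.uint8)
    labels[kidney_region] = 1
    labels[collecting] = 2

    bg, par, con = spec.intensities
    ct = np.full(tuple(shape), bg, dtype=np.float64)
    ct[labels == 1] = par
    ct[labels == 2] = con
    if spec.noise_sd > 0:
        ct = ct + rng.normal(0.0, spec.noise_sd, size=ct.shape)

    sp = tuple(spacing)
    truth = PhantomTruth(
        ct=Volume(ct, sp),
        labels=LabelMap(labels, sp),
        centerline=centerline,
        spec=spec,
    )
    # containment invariant: centerline voxels carry the collecting label
    for poly in centerline:
        for a, b in zip(poly[:-1], poly[1:]):
            n = max(int(np.ceil(np.linalg.norm(b - a))), 1)
            for t in np.linspace(0, 1, n + 1):
                idx = tuple(np.clip((a + t * (b - a)) / spacing, 0,
                                    shape - 1).astype(int))
                if labels[idx] != 2:
                    raise RuntimeError("centerline point escaped the collecting system")
    return truth


def _low_freq_noise(shape, rng: np.random.Generator, cells: int = 6) -> np.ndarray:
    coarse = rng.normal(0, 1, size=(cells, cells))
    return ndimage.zoom(coarse, (shape[0] / cells, shape[1] / cells), order=1)


def make_style_domain(images, rng_seed: int = 0) -> list[np.ndarray]:
    """Map grayscale-ish renders to a synthetic endoscopy-style tissue domain.

    Luminance drives a pinkish palette (channel means ordered R > G >= B),
    modulated by low-frequency mottling, a radial vignette (corners darker
    than centre), and a couple of bright specular blobs.  Deterministic
    under ``rng_seed``.
    """
    images = list(images)
    if not images:
        raise ValueError("make_style_domain requires a non-empty image set")
    rng = np.random.default_rng(rng_seed)
    out = []
    for img in images:
        img = np.asarray(img, dtype=np.float64)
        lum = img.mean(axis=2)
        h, w = lum.shape
        mottle = 1.0 + 0.08 * _low_freq_noise((h, w), rng)
        yy, xx = np.mgrid[0:h, 0:w]
        r2 = ((yy - (h - 1) / 2) / (h / 2)) ** 2 + ((xx - (w - 1) / 2) / (w / 2)) ** 2
        vignette = 1.0 - 0.45 * np.clip(r2 / 2.0, 0.0, 1.0)
        # palette anchored to the source luminance: endoscopic cavities are
        # dark, and a bright fixed offset would let overall brightness (not
        # illumination structure) dominate distribution distances
        base = lum * mottle * vignette
        styled = np.stack([
            0.16 + 0.62 * base,   # R
            0.06 + 0.30 * base,   # G
            0.05 + 0.24 * base,   # B
        ], axis=2)
        for _ in range(2):  # specular blobs
            cy, cx = rng.uniform(0.2, 0.8) * h, rng.uniform(0.2, 0.8) * w
            sig = rng.uniform(0.02, 0.05) * max(h, w)
            blob = np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sig ** 2)))
            styled += 0.5 * blob[..., None]
        out.append(np.clip(styled, 0.0, 1.0))
    return out
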