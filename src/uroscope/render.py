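"""Endoscopy-style rendering: camera paths along the skeleton and ray-cast
Phong shading.

Camera poses are sampled at fixed arc-length intervals along a depth-first
traversal of the skeleton edges, looking along the local tangent with the
up vector parallel-transported so the view does not roll at branch turns.

The renderer casts one primary ray per pixel (pinhole camera), intersects
it with the mesh (Möller–Trumbore, chunked for memory), and shades the
first hit with the Phong model

    I = ambient*C + diffuse*C*max(0, n·l) + specular*max(0, r·v)^m

Three presets reproduce the lighting configurations used for virtual
ureteroscopy:

* ``baseline`` — 0% ambient, 100% diffuse, 0% specular, global light,
  wireframe edges overlaid in preset contrasting colors.
* ``customsurface`` — 100% ambient, 30% diffuse, global light, edges on.
* ``customlight`` — 0% ambient, 50% diffuse, 10% specular, a headlight
  just behind the camera (imitating the scope's own light), no edges.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .meshing import TriangleMesh
from .skeleton import Skeleton

__all__ = [
    "CameraPose",
    "LightingConfig",
    "PRESETS",
    "sample_trajectory",
    "render",
]

_DEFAULT_PALETTE = (
    (0.9, 0.2, 0.2), (0.2, 0.9, 0.2), (0.2, 0.4, 0.9), (0.9, 0.9, 0.2), (0.2, 0.9, 0.9),
)


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length vector")
    return v / n


@dataclasses.dataclass
class CameraPose:
    """Pinhole camera pose: position (mm), unit view direction, unit up ⟂ view."""

    position: np.ndarray
    view_dir: np.ndarray
    up: np.ndarray
    vfov_deg: float = 60.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=np.float64)
        self.view_dir = _unit(np.asarray(self.view_dir, dtype=np.float64))
        self.up = _unit(np.asarray(self.up, dtype=np.float64))
        if abs(float(self.view_dir @ self.up)) > 1e-6:
            raise ValueError("up vector must be orthogonal to view_dir")
        if not (0 < self.vfov_deg < 180):
            raise ValueError("vfov_deg must be in (0, 180)")

    def to_dict(self) -> dict:
        return {"position": self.position.tolist(), "view_dir": self.view_dir.tolist(),
                "up": self.up.tolist(), "vfov_deg": self.vfov_deg}


@dataclasses.dataclass
class LightingConfig:
    """Phong shading configuration; fractions in [0, 1].

    ``headlight`` places the light 1 mm behind the camera along the view
    axis (endoscope illumination); otherwise a fixed directional scene
    light is used.  ``distance_falloff`` enables inverse-square attenuation
    of the headlight (off by default: scene lights have fixed intensity).
    """

    ambient: float = 0.0
    diffuse: float = 1.0
    specular: float = 0.0
    specular_exponent: float = 20.0
    headlight: bool = False
    headlight_offset_mm: float = 1.0
    distance_falloff: bool = False
    render_edges: bool = False
    edge_palette: tuple = _DEFAULT_PALETTE
    edge_width: float = 0.06  # barycentric threshold for wireframe overlay
    light_direction: tuple = (0.0, 0.0, 1.0)  # used when headlight is off
    base_color: tuple = (0.78, 0.78, 0.78)
    background: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        for name in ("ambient", "diffuse", "specular"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.specular_exponent <= 0:
            raise ValueError("specular_exponent must be > 0")


PRESETS: dict[str, LightingConfig] = {
    "baseline": LightingConfig(ambient=0.0, diffuse=1.0, specular=0.0,
                               headlight=False, render_edges=True),
    "customsurface": LightingConfig(ambient=1.0, diffuse=0.3, specular=0.0,
                                    headlight=False, render_edges=True),
    "customlight": LightingConfig(ambient=0.0, diffuse=0.5, specular=0.1,
                                  headlight=True, render_edges=False),
}

_WORLD_UP = np.array([0.0, 0.0, 1.0])


def _initial_up(tangent: np.ndarray) -> np.ndarray:
    up = _WORLD_UP - (_WORLD_UP @ tangent) * tangent
    if np.linalg.norm(up) < 1e-8:
        alt = np.array([0.0, 1.0, 0.0])
        up = alt - (alt @ tangent) * tangent
    return _unit(up)


def _transport(up_prev: np.ndarray, tangent: np.ndarray) -> np.ndarray:
    up = up_prev - (up_prev @ tangent) * tangent
    if np.linalg.norm(up) < 1e-8:
        return _initial_up(tangent)
    return _unit(up)


def _dfs_chains(skel: Skeleton) -> list[list[int]]:
    """Depth-first traversal of skeleton edges as a list of node-index chains."""
    adj: dict[int, list[int]] = {i: [] for i in range(skel.n_nodes)}
    for i, j in skel.edges:
        adj[int(i)].append(int(j))
        adj[int(j)].append(int(i))
    for v in adj.values():
        v.sort()
    deg = skel.degrees()
    visited_edges: set[tuple[int, int]] = set()
    chains: list[list[int]] = []
    # root at the lowest-index degree-1 node (tube entry) when one exists
    tips = np.flatnonzero(deg == 1)
    order = [int(tips[0])] if len(tips) else [0]
    order += [i for i in range(skel.n_nodes) if i != order[0]]
    for root in order:
        stack = [root]
        while stack:
            u = stack.pop()
            for w in adj[u]:
                key = (min(u, w), max(u, w))
                if key in visited_edges:
                    continue
                # walk a chain as far as it goes depth-first
                chain = [u, w]
                visited_edges.add(key)
                cur, prev = w, u
                while True:
                    nxt = [x for x in adj[cur]
                           if (min(cur, x), max(cur, x)) not in visited_edges]
                    if not nxt:
                        break
                    x = nxt[0]
                    visited_edges.add((min(cur, x), max(cur, x)))
                    chain.append(x)
                    prev, cur = cur, x
                    stack.append(prev)
                chains.append(chain)
                stack.append(u)
    return chains


def sample_trajectory(skel: Skeleton, spacing_mm: float,
                      vfov_deg: float = 60.0) -> list[CameraPose]:
    """Place camera poses at fixed arc-length intervals along the skeleton.

    Edges are traversed depth-first from a degree-1 node; each contiguous
    chain is sampled at ``spacing_mm`` intervals, endpoints included.  The
    view direction is the local tangent (traversal direction) and the up
    vector is parallel-transported along each chain.
    """
    if len(skel.edges) == 0:
        raise ValueError("skeleton has no edges; cannot build a trajectory")
    if spacing_mm <= 0:
        raise ValueError("spacing_mm must be > 0")
    poses: list[CameraPose] = []
    for chain in _dfs_chains(skel):
        pts = skel.nodes[chain]
        seg = np.diff(pts, axis=0)
        seg_len = np.linalg.norm(seg, axis=1)
        good = seg_len > 1e-12
        if not good.any():
            continue
        cum = np.concatenate([[0.0], np.cumsum(seg_len)])
        total = cum[-1]
        s_values = list(np.arange(0.0, total + 1e-9, spacing_mm))
        if total - s_values[-1] > 1e-9:
            s_values.append(total)
        up = None
        for s in s_values:
            k = min(int(np.searchsorted(cum, s, side="right")) - 1, len(seg) - 1)
            while not good[k]:
                k -= 1
            t = _unit(seg[k])
            frac = (s - cum[k]) / seg_len[k]
            pos = pts[k] + frac * seg[k]
            up = _initial_up(t) if up is None else _transport(up, t)
            poses.append(CameraPose(pos, t, up, vfov_deg))
    return poses


def _raycast(origin: np.ndarray, dirs: np.ndarray, mesh: TriangleMesh,
             max_pairs: int = 4_000_000):
    """First-hit ray casting (Möller–Trumbore).  Returns (t, tri, u, v) per ray.

    With a shared origin every per-triangle cross product is precomputable:
    using triple-product identities, det = -d·(e1×e2), u·det = -d·(tvec×e2),
    v·det = d·(tvec×e1) and t·det = e2·(tvec×e1), so each ray chunk costs
    three (rays × triangles) matmuls.
    """
    v0 = mesh.vertices[mesh.faces[:, 0]]
    e1 = mesh.vertices[mesh.faces[:, 1]] - v0
    e2 = mesh.vertices[mesh.faces[:, 2]] - v0
    tvec = origin[None, :] - v0                    # (M, 3), origin shared
    n_geom = np.cross(e1, e2)                      # (M, 3)
    te2 = np.cross(tvec, e2)                       # (M, 3)
    qvec = np.cross(tvec, e1)                      # (M, 3)
    t_num = np.einsum("ij,ij->i", e2, qvec)        # (M,)
    m = len(v0)
    n = len(dirs)
    chunk = max(1, min(n, max_pairs // max(m, 1)))
    best_t = np.full(n, np.inf)
    best_tri = np.full(n, -1, dtype=np.int64)
    best_u = np.zeros(n)
    best_v = np.zeros(n)
    for s in range(0, n, chunk):
        d = dirs[s:s + chunk]                      # (r, 3)
        det = -(d @ n_geom.T)                      # (r, M)
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = np.where(np.abs(det) > 1e-12, 1.0 / det, 0.0)
        u = -(d @ te2.T) * inv
        v = (d @ qvec.T) * inv
        t = t_num[None, :] * inv
        valid = ((np.abs(det) > 1e-12) & (u >= -1e-9) & (v >= -1e-9)
                 & (u + v <= 1 + 1e-9) & (t > 1e-6))
        t = np.where(valid, t, np.inf)
        idx = np.argmin(t, axis=1)
        rows = np.arange(len(d))
        tmin = t[rows, idx]
        hit = tmin < best_t[s:s + chunk]
        best_t[s:s + chunk][hit] = tmin[hit]
        best_tri[s:s + chunk][hit] = idx[hit]
        best_u[s:s + chunk][hit] = u[rows, idx][hit]
        best_v[s:s + chunk][hit] = v[rows, idx][hit]
    return best_t, best_tri, best_u, best_v


def render(mesh: TriangleMesh, pose: CameraPose, cfg: LightingConfig,
           resolution: tuple[int, int] = (128, 128)) -> np.ndarray:
    """Render one frame; returns an (H, W, 3) array in [0, 1].

    Rays that miss the mesh get the background color; hits are shaded with
    the Phong model (normals flipped toward the camera so tube interiors
    are lit).  With ``render_edges`` pixels near a triangle edge (small
    minimum barycentric coordinate) are overlaid with a palette color keyed
    to the triangle index.
    """
    h, w = int(resolution[0]), int(resolution[1])
    if h < 1 or w < 1:
        raise ValueError("resolution must be positive")
    f = pose.view_dir
    right = _unit(np.cross(f, pose.up))
    up = pose.up
    tan_half = np.tan(np.deg2rad(pose.vfov_deg) / 2.0)
    aspect = w / h
    ys = (1.0 - 2.0 * (np.arange(h) + 0.5) / h) * tan_half
    xs = (2.0 * (np.arange(w) + 0.5) / w - 1.0) * tan_half * aspect
    dirs = (f[None, None, :]
            + ys[:, None, None] * up[None, None, :]
            + xs[None, :, None] * right[None, None, :])
    dirs = dirs / np.linalg.norm(dirs, axis=2, keepdims=True)
    dirs_flat = dirs.reshape(-1, 3)

    t, tri, bu, bv = _raycast(pose.position, dirs_flat, mesh)
    img = np.empty((h * w, 3))
    img[:] = np.asarray(cfg.background, dtype=np.float64)
    hit = tri >= 0
    if hit.any():
        hit_idx = np.flatnonzero(hit)
        tri_h = tri[hit_idx]
        d = dirs_flat[hit_idx]
        points = pose.position[None, :] + t[hit_idx, None] * d
        v0 = mesh.vertices[mesh.faces[tri_h, 0]]
        e1 = mesh.vertices[mesh.faces[tri_h, 1]] - v0
        e2 = mesh.vertices[mesh.faces[tri_h, 2]] - v0
        n = np.cross(e1, e2)
        n = n / np.linalg.norm(n, axis=1, keepdims=True)
        flip = np.einsum("ij,ij->i", n, d) > 0  # face the camera
        n[flip] = -n[flip]
        if cfg.headlight:
            light_pos = pose.position - cfg.headlight_offset_mm * pose.view_dir
            l_vec = light_pos[None, :] - points
            l_dist = np.linalg.norm(l_vec, axis=1, keepdims=True)
            l = l_vec / l_dist
            atten = 1.0 / np.maximum(l_dist[:, 0] ** 2, 1e-6) if cfg.distance_falloff else 1.0
        else:
            l = np.broadcast_to(_unit(np.asarray(cfg.light_direction, dtype=np.float64)),
                                points.shape)
            atten = 1.0
        ndotl = np.maximum(0.0, np.einsum("ij,ij->i", n, l))
        view = -d
        refl = 2.0 * np.einsum("ij,ij->i", l, n)[:, None] * n - l
        rdotv = np.maximum(0.0, np.einsum("ij,ij->i", refl, view))
        c = np.asarray(cfg.base_color, dtype=np.float64)
        shade = (cfg.ambient * c[None, :]
                 + cfg.diffuse * (atten * ndotl)[:, None] * c[None, :]
                 + cfg.specular * (atten * rdotv ** cfg.specular_exponent)[:, None])
        if cfg.render_edges:
            bw = 1.0 - bu[hit_idx] - bv[hit_idx]
            near_edge = np.minimum(np.minimum(bu[hit_idx], bv[hit_idx]), bw) < cfg.edge_width
            palette = np.asarray(cfg.edge_palette, dtype=np.float64)
            shade[near_edge] = palette[tri_h[near_edge] % len(palette)]
        img[hit_idx] = shade
    return np.clip(img.reshape(h, w, 3), 0.0, 1.0)
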