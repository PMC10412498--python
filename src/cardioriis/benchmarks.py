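"""Canonical verification geometries for the flow solver.

A straight cylindrical channel (pressure-driven Poiseuille flow has the
closed form ``u_max = dp R^2 / (4 mu L)``) and the same channel with a
membrane spanning the lumen (the resistive-surface blocking benchmark).
SI units here: these meshes feed the solver directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay

from . import fem

__all__ = ["ChannelMesh", "cylinder_channel", "membrane_surface"]

TAG_WALL, TAG_INLET, TAG_OUTLET = 0, 1, 2


@dataclass
class ChannelMesh:
    nodes: np.ndarray  # (N,3) meters
    tets: np.ndarray
    bfaces: np.ndarray
    bface_tag: np.ndarray
    radius: float
    length: float

    @property
    def wall_nodes(self):
        return np.unique(self.bfaces[self.bface_tag == TAG_WALL])

    def faces_of(self, tag: int) -> np.ndarray:
        return self.bfaces[self.bface_tag == tag]


def cylinder_channel(radius: float = 5e-3, length: float = 2e-2,
                     h: float = 1.2e-3, seed: int = 0) -> ChannelMesh:
    """Tet mesh of a cylinder along z in [0, length]; inlet z=0, outlet z=L."""
    rng = np.random.default_rng(seed)

    def sdf(p):
        r = np.linalg.norm(p[:, :2], axis=1)
        return np.maximum.reduce([r - radius, p[:, 2] - length, -p[:, 2]])

    lo = np.array([-radius - h, -radius - h, -h])
    hi = np.array([radius + h, radius + h, length + h])
    axes = [np.arange(lo[k], hi[k] + h / 2, h) for k in range(3)]
    g = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    f = sdf(g)
    interior = g[f < -0.45 * h]
    interior = interior + rng.uniform(-0.08 * h, 0.08 * h, interior.shape)
    interior[:, 2] = np.clip(interior[:, 2], 0.05 * h, length - 0.05 * h)
    near = g[np.abs(f) < 0.9 * h]
    # project onto whichever boundary sheet is locally active
    surf = near.copy()
    r = np.linalg.norm(surf[:, :2], axis=1)
    band = 0.9 * h
    lat = np.abs(r - radius) < band
    rr = np.where(r[lat] > 1e-12, r[lat], 1.0)
    surf[lat, :2] *= (radius / rr)[:, None]
    top = np.abs(surf[:, 2] - length) < band
    surf[top, 2] = length
    bot = np.abs(surf[:, 2]) < band
    surf[bot, 2] = 0.0
    surf = surf[lat | top | bot]
    inside_caps = np.linalg.norm(surf[:, :2], axis=1) <= radius + 1e-12
    surf = surf[inside_caps]
    key = np.round(surf / (0.62 * h)).astype(np.int64)
    _, keep = np.unique(key, axis=0, return_index=True)
    surf = surf[np.sort(keep)]
    pts = np.vstack([interior, surf])

    dela = Delaunay(pts)
    cent = pts[dela.simplices].mean(axis=1)
    vols = np.abs(fem.tet_volumes(pts, dela.simplices))
    keep = (sdf(cent) < 0.0) & (vols > 1e-4 * h**3)
    tets_full = dela.simplices[keep]
    used = np.unique(tets_full)
    remap = np.full(len(pts), -1)
    remap[used] = np.arange(len(used))
    nodes = pts[used]
    tets = remap[tets_full]
    sv = fem.tet_volumes(nodes, tets)
    tets[sv < 0] = tets[sv < 0][:, [0, 1, 3, 2]]

    bfaces, _ = fem.boundary_faces(tets)
    fc = nodes[bfaces].mean(axis=1)
    tol = 0.3 * h
    tag = np.full(len(bfaces), TAG_WALL)
    tag[np.abs(fc[:, 2]) < tol] = TAG_INLET
    tag[np.abs(fc[:, 2] - length) < tol] = TAG_OUTLET
    return ChannelMesh(nodes, tets, bfaces, tag, radius, length)


def membrane_surface(radius: float, z0: float, edge: float = 6e-4):
    """Triangulated disk spanning the channel lumen at height z0."""
    n_r = max(3, int(round(radius / edge)))
    n_az = max(12, int(round(2 * np.pi * radius / edge)))
    rads = np.linspace(0.0, radius, n_r + 1)[1:]
    th = np.linspace(0.0, 2 * np.pi, n_az, endpoint=False)
    Rg, Tg = np.meshgrid(rads, th, indexing="ij")
    ring_pts = np.column_stack(
        [
            (Rg * np.cos(Tg)).ravel(),
            (Rg * np.sin(Tg)).ravel(),
            np.full(Rg.size, z0),
        ]
    )
    verts = np.vstack([[0.0, 0.0, z0], ring_pts])
    gid = 1 + np.arange(n_r)[:, None] * n_az + np.arange(n_az)[None, :]
    fan = np.stack([np.zeros(n_az, int), gid[0], np.roll(gid[0], -1)], axis=1)
    i = np.arange(n_r - 1)[:, None]
    j = np.arange(n_az)[None, :]
    jp = (j + 1) % n_az
    q1 = np.stack([gid[i, j], gid[i + 1, j], gid[i + 1, jp]], axis=-1)
    q2 = np.stack([gid[i, j], gid[i + 1, jp], gid[i, jp]], axis=-1)
    faces = np.vstack([fan, q1.reshape(-1, 3), q2.reshape(-1, 3)])
    return verts, faces
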