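"""Planar cross-sections of a tetrahedral mesh (marching tetrahedra).

Used for flow rates through named sections (LVOT, mitral orifice, outlet
planes), area-weighted slice-average pressures, and velocity maxima.  Cut
points are convex combinations of two mesh nodes, so any nodal field can be
interpolated onto the section exactly in the P1 sense.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PlaneSection", "plane_section", "SlicePlan"]


@dataclass
class SlicePlan:
    """Named planar sections: {name: (origin, unit normal)} plus an optional
    region mask name -> element selector."""

    sections: dict

    def __post_init__(self):
        for name, (origin, normal) in self.sections.items():
            n = np.linalg.norm(normal)
            if not np.isclose(n, 1.0, atol=1e-8):
                self.sections[name] = (np.asarray(origin, float),
                                       np.asarray(normal, float) / n)


class PlaneSection:
    """Triangulated mesh-plane intersection with interpolation weights."""

    def __init__(self, node_a, node_b, frac, tris, normal):
        # cut point k = (1-frac[k]) x[node_a[k]] + frac[k] x[node_b[k]]
        self.node_a = node_a
        self.node_b = node_b
        self.frac = frac
        self.tris = tris  # (T,3) indices into cut points
        self.normal = normal

    @property
    def n_triangles(self) -> int:
        return len(self.tris)

    def points(self, nodes: np.ndarray) -> np.ndarray:
        return (
            (1.0 - self.frac)[:, None] * nodes[self.node_a]
            + self.frac[:, None] * nodes[self.node_b]
        )

    def interpolate(self, field: np.ndarray) -> np.ndarray:
        fa = field[self.node_a]
        fb = field[self.node_b]
        if field.ndim == 1:
            return (1.0 - self.frac) * fa + self.frac * fb
        return (1.0 - self.frac)[:, None] * fa + self.frac[:, None] * fb

    def tri_areas(self, nodes: np.ndarray) -> np.ndarray:
        p = self.points(nodes)[self.tris]
        cr = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
        return np.linalg.norm(cr, axis=1) / 2.0

    def area(self, nodes: np.ndarray) -> float:
        return float(self.tri_areas(nodes).sum())

    def flux(self, nodes: np.ndarray, u: np.ndarray) -> float:
        """Integral of u . n over the section (exact for P1 fields)."""
        un = self.interpolate(u) @ self.normal
        tri_mean = un[self.tris].mean(axis=1)
        return float((tri_mean * self.tri_areas(nodes)).sum())

    def average(self, nodes: np.ndarray, f: np.ndarray) -> float:
        """Area-weighted mean of a nodal scalar over the section."""
        fv = self.interpolate(f)
        tri_mean = fv[self.tris].mean(axis=1)
        a = self.tri_areas(nodes)
        tot = a.sum()
        if tot == 0:
            raise ValueError("empty plane section")
        return float((tri_mean * a).sum() / tot)

    def max_magnitude(self, u: np.ndarray) -> float:
        uv = self.interpolate(u)
        if uv.ndim == 1:
            return float(np.abs(uv).max(initial=0.0))
        return float(np.linalg.norm(uv, axis=1).max(initial=0.0))


def plane_section(nodes: np.ndarray, tets: np.ndarray, origin, normal,
                  elem_mask: np.ndarray | None = None) -> PlaneSection:
    """Intersect the mesh with the plane through ``origin`` with ``normal``.

    ``elem_mask`` restricts the cut to a subset of elements (e.g. one
    anatomical region).  Raises if the intersection is empty.
    """
    origin = np.asarray(origin, float)
    normal = np.asarray(normal, float)
    normal = normal / np.linalg.norm(normal)
    sd = (nodes - origin) @ normal
    s = sd[tets]  # (E,4)
    pos = s > 0.0
    npos = pos.sum(axis=1)
    cut = (npos > 0) & (npos < 4)
    if elem_mask is not None:
        cut &= elem_mask
    if not cut.any():
        raise ValueError("plane does not intersect the (selected) mesh")

    pa_parts, pb_parts, fr_parts, tri_parts = [], [], [], []
    n_pts = 0

    def cut_edges(rows, local_pairs):
        """Interpolation data for the given local edges of the given rows."""
        la = np.array([p[0] for p in local_pairs])
        lb = np.array([p[1] for p in local_pairs])
        na = tets[rows][:, la]
        nb = tets[rows][:, lb]
        sa = s[rows][:, la]
        sb = s[rows][:, lb]
        return na, nb, sa / (sa - sb)

    # 1-vs-3 and 3-vs-1 cases: a single triangle from the three edges
    # incident to the lone vertex
    for lone_pos in (True, False):
        want = 1 if lone_pos else 3
        rows = np.where(cut & (npos == want))[0]
        if len(rows) == 0:
            continue
        lone = np.argmax(pos[rows] == lone_pos, axis=1)
        other = np.array([[v for v in range(4) if v != l] for l in lone])
        na = np.take_along_axis(tets[rows], lone[:, None], axis=1).repeat(3, 1)
        nb = np.take_along_axis(tets[rows], other, axis=1)
        sa = np.take_along_axis(s[rows], lone[:, None], axis=1).repeat(3, 1)
        sb = np.take_along_axis(s[rows], other, axis=1)
        fr = sa / (sa - sb)
        m = len(rows)
        pa_parts.append(na.ravel())
        pb_parts.append(nb.ravel())
        fr_parts.append(fr.ravel())
        tri_parts.append(n_pts + 3 * np.arange(m)[:, None] + np.array([[0, 1, 2]]))
        n_pts += 3 * m

    # 2-vs-2 cases: a quad ordered so consecutive points share a vertex
    rows22 = np.where(cut & (npos == 2))[0]
    if len(rows22):
        p = pos[rows22]
        # vertex 0's same-side partner determines the cyclic edge pattern
        partner = 1 + np.argmax(p[:, 1:] == p[:, :1], axis=1)
        groups = {
            1: [(0, 2), (0, 3), (1, 3), (1, 2)],
            2: [(0, 1), (0, 3), (2, 3), (2, 1)],
            3: [(0, 1), (0, 2), (3, 2), (3, 1)],
        }
        for j, cyc in groups.items():
            sel = rows22[partner == j]
            if len(sel) == 0:
                continue
            la = np.array([c[0] for c in cyc])
            lb = np.array([c[1] for c in cyc])
            na = tets[sel][:, la]
            nb = tets[sel][:, lb]
            sa = s[sel][:, la]
            sb = s[sel][:, lb]
            fr = sa / (sa - sb)
            m = len(sel)
            pa_parts.append(na.ravel())
            pb_parts.append(nb.ravel())
            fr_parts.append(fr.ravel())
            base = n_pts + 4 * np.arange(m)[:, None]
            tri_parts.append(base + np.array([[0, 1, 2]]))
            tri_parts.append(base + np.array([[0, 2, 3]]))
            n_pts += 4 * m
    return PlaneSection(
        node_a=np.concatenate(pa_parts),
        node_b=np.concatenate(pb_parts),
        frac=np.concatenate(fr_parts),
        tris=np.vstack(tri_parts),
        normal=normal,
    )
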