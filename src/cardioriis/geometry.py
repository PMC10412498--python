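"""Analytic left-heart geometry and tetrahedral meshing.

The cavity is a union of three implicit primitives with closed-form volumes
(lengths in mm throughout):

- *ventricle*: a prolate ellipsoid truncated at the valvular base plane
  ``z = 0`` (apex pointing down),
- *atrium*: a sphere poking through the base plane; its cross-section at
  ``z = 0`` is the mitral annulus; truncated on top by the atrial outlet
  plane ``z = sigma1_z`` (outlet Sigma1, normal +z),
- *aorta*: a tilted circular tube starting below the base plane (so its
  cross-section at ``z = 0`` is the aortic orifice) and cut by a plane
  normal to its axis (outlet Sigma2).

Meshing is grid-seeded Delaunay with boundary projection: interior lattice
points (jittered to break cospherical ties) plus near-surface points
projected onto the zero level set, a Delaunay triangulation of the cloud,
and a centroid-inside filter.  The boundary of the kept tetrahedra is a
closed, consistently oriented triangle surface, so cavity volumes computed
by the divergence theorem are exact for the discrete shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, cKDTree

from . import fem

__all__ = ["HeartPrimitives", "HeartMesh", "build_mesh", "PointLocator"]

REGION_VENTRICLE, REGION_ATRIUM, REGION_AORTA = 0, 1, 2
TAG_WALL, TAG_ATRIAL_OUTLET, TAG_AORTIC_OUTLET = 0, 1, 2


@dataclass
class HeartPrimitives:
    """Implicit description of the cavity (mm)."""

    vent_axes: tuple[float, float, float] = (24.0, 24.0, 46.0)
    vent_center_z: float = -8.0
    atrium_center: tuple[float, float, float] = (-11.5, 0.0, 15.12)
    atrium_radius: float = 19.0
    sigma1_z: float = 26.14
    aorta_origin: tuple[float, float, float] = (15.0, 0.0, 0.0)
    aorta_tilt_deg: float = 42.0
    aorta_radius: float = 8.0
    aorta_length: float = 32.0  # along the axis, measured from the origin

    @property
    def aorta_dir(self) -> np.ndarray:
        th = np.deg2rad(self.aorta_tilt_deg)
        return np.array([np.sin(th), 0.0, np.cos(th)])

    @property
    def annulus_radius(self) -> float:
        """Radius of the mitral annulus: atrium sphere cut at z = 0."""
        cz = self.atrium_center[2]
        return float(np.sqrt(self.atrium_radius**2 - cz**2))

    @property
    def annulus_center(self) -> np.ndarray:
        return np.array([self.atrium_center[0], self.atrium_center[1], 0.0])

    def scaled(self, factor: float) -> "HeartPrimitives":
        """Similarity scaling about the origin (used for the dilated scenario)."""
        return HeartPrimitives(
            vent_axes=tuple(a * factor for a in self.vent_axes),
            vent_center_z=self.vent_center_z * factor,
            atrium_center=tuple(c * factor for c in self.atrium_center),
            atrium_radius=self.atrium_radius * factor,
            sigma1_z=self.sigma1_z * factor,
            aorta_origin=tuple(c * factor for c in self.aorta_origin),
            aorta_tilt_deg=self.aorta_tilt_deg,
            aorta_radius=self.aorta_radius * factor,
            aorta_length=self.aorta_length * factor,
        )

    # ---- implicit fields -------------------------------------------------
    def sdf_ventricle(self, pts: np.ndarray) -> np.ndarray:
        a, b, c = self.vent_axes
        q = np.empty_like(pts)
        q[:, 0] = pts[:, 0] / a
        q[:, 1] = pts[:, 1] / b
        q[:, 2] = (pts[:, 2] - self.vent_center_z) / c
        r = np.linalg.norm(q, axis=1)
        grad = np.empty_like(pts)
        grad[:, 0] = q[:, 0] / a
        grad[:, 1] = q[:, 1] / b
        grad[:, 2] = q[:, 2] / c
        gn = np.linalg.norm(grad, axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            d = (r - 1.0) * r / gn  # first-order distance estimate
        d[~np.isfinite(d)] = -min(a, b, c)
        return np.maximum(d, pts[:, 2])  # truncate at base plane z <= 0

    def sdf_atrium(self, pts: np.ndarray) -> np.ndarray:
        d = np.linalg.norm(pts - np.asarray(self.atrium_center), axis=1)
        return np.maximum(d - self.atrium_radius, pts[:, 2] - self.sigma1_z)

    def sdf_aorta(self, pts: np.ndarray) -> np.ndarray:
        # tube truncated by the base plane z = 0, which passes through the
        # axis origin: the cavity below the plane belongs to the ventricle
        rel = pts - np.asarray(self.aorta_origin)
        s = rel @ self.aorta_dir
        perp = np.linalg.norm(rel - s[:, None] * self.aorta_dir, axis=1)
        d = perp - self.aorta_radius
        return np.maximum.reduce([d, s - self.aorta_length, -pts[:, 2]])

    def sdf(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return np.minimum.reduce(
            [self.sdf_ventricle(pts), self.sdf_atrium(pts), self.sdf_aorta(pts)]
        )

    def region_label(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        stack = np.stack(
            [self.sdf_ventricle(pts), self.sdf_atrium(pts), self.sdf_aorta(pts)]
        )
        return stack.argmin(axis=0)

    def inside(self, pts: np.ndarray) -> np.ndarray:
        return self.sdf(pts) < 0.0

    def bbox(self, margin: float = 3.0):
        a, b, c = self.vent_axes
        acx, acy, acz = self.atrium_center
        top = np.asarray(self.aorta_origin) + self.aorta_length * self.aorta_dir
        lo = np.array(
            [
                min(-a, acx - self.atrium_radius) - margin,
                min(-b, acy - self.atrium_radius) - margin,
                self.vent_center_z - c - margin,
            ]
        )
        hi = np.array(
            [
                max(a, acx + self.atrium_radius, top[0] + self.aorta_radius) + margin,
                max(b, acy + self.atrium_radius, self.aorta_radius) + margin,
                max(self.sigma1_z, top[2] + self.aorta_radius) + margin,
            ]
        )
        return lo, hi

    def junction_ring_distance(self, pts: np.ndarray) -> np.ndarray:
        """Distance to the concave junction curves of the union (annulus
        ring, aortic orifice ring, outlet rims, equator rim).

        The min-of-sdf composition underestimates distances near these
        creases, so the mesher keeps interior seeds away from them.
        """
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        a, b, c = self.vent_axes
        acx, acy, _ = self.atrium_center
        out = np.full(len(pts), np.inf)

        def ring_z(center_xy, radius, zplane):
            rho = np.hypot(pts[:, 0] - center_xy[0], pts[:, 1] - center_xy[1])
            return np.hypot(rho - radius, pts[:, 2] - zplane)

        # mitral annulus and atrial outlet rim (sphere cut circles)
        out = np.minimum(out, ring_z((acx, acy), self.annulus_radius, 0.0))
        cz = self.atrium_center[2]
        cap_r = np.sqrt(max(self.atrium_radius**2 - (self.sigma1_z - cz) ** 2, 0.0))
        out = np.minimum(out, ring_z((acx, acy), cap_r, self.sigma1_z))
        # ventricle equator rim at the base plane
        eq_r = a * np.sqrt(max(1.0 - (self.vent_center_z / c) ** 2, 0.0))
        out = np.minimum(out, ring_z((0.0, 0.0), eq_r, 0.0))
        # aortic orifice (approximate: circle of the widened section) and cap rim
        th = np.deg2rad(self.aorta_tilt_deg)
        out = np.minimum(
            out, ring_z((self.aorta_origin[0], self.aorta_origin[1]),
                        self.aorta_radius / np.cos(th), 0.0)
        )
        d = self.aorta_dir
        rel = pts - (np.asarray(self.aorta_origin) + self.aorta_length * d)
        s = rel @ d
        rho = np.linalg.norm(rel - s[:, None] * d, axis=1)
        out = np.minimum(out, np.hypot(rho - self.aorta_radius, s))
        return out

    def project(self, pts: np.ndarray, iters: int = 6, eps: float = 1e-3) -> np.ndarray:
        """Project points onto the zero level set (first-order Newton steps)."""
        x = np.array(pts, dtype=float)
        for _ in range(iters):
            f = self.sdf(x)
            grad = np.empty_like(x)
            for k in range(3):
                dp = np.zeros(3)
                dp[k] = eps
                grad[:, k] = (self.sdf(x + dp) - self.sdf(x - dp)) / (2 * eps)
            gn2 = np.einsum("ij,ij->i", grad, grad)
            gn2[gn2 < 1e-12] = 1.0
            x -= (f / gn2)[:, None] * grad
        return x

    # ---- closed-form volume ---------------------------------------------
    def analytic_volume(self) -> float:
        """Exact cavity volume of the implicit union (mm^3).

        Ellipsoid cap below z=0 + atrium sphere truncated above z=0 and
        below sigma1_z + aortic tube above z=0 (the parts of sphere and
        tube below the base plane lie inside the ellipsoid).
        """
        a, b, c = self.vent_axes
        # ellipsoid cap z < 0: cap height measured from the bottom
        h = c + min(0.0 - self.vent_center_z, c)
        vol_vent = np.pi * a * b / c**2 * h**2 * (c - h / 3.0)
        r = self.atrium_radius

        def sphere_below(zplane: float) -> float:
            hh = np.clip(zplane - (self.atrium_center[2] - r), 0.0, 2 * r)
            return np.pi * hh**2 * (3 * r - hh) / 3.0

        vol_atr = sphere_below(self.sigma1_z) - sphere_below(0.0)
        # base plane passes through the axis origin, so the oblique cut
        # removes symmetric wedges: tube volume above it is exactly
        # pi r^2 L
        vol_ao = np.pi * self.aorta_radius**2 * self.aorta_length
        return float(vol_vent + vol_atr + vol_ao)


@dataclass
class HeartMesh:
    """Tagged tetrahedral mesh of the cavity (coordinates mm)."""

    nodes: np.ndarray  # (N,3)
    tets: np.ndarray  # (E,4), positively oriented
    elem_region: np.ndarray  # (E,) primitive label
    bfaces: np.ndarray  # (F,3) outward-oriented boundary triangles
    bface_tag: np.ndarray  # (F,) TAG_*
    bface_owner: np.ndarray  # (F,) owning element
    primitives: HeartPrimitives
    locator: "PointLocator | None" = field(default=None, repr=False)
    _tag_tol: float = 1.0

    @property
    def wall_nodes(self) -> np.ndarray:
        return np.unique(self.bfaces[self.bface_tag == TAG_WALL])

    def outlet_nodes(self, tag: int) -> np.ndarray:
        """Outlet nodes excluding any shared with the wall (wall wins)."""
        nodes = np.unique(self.bfaces[self.bface_tag == tag])
        return np.setdiff1d(nodes, self.wall_nodes)

    @property
    def boundary_nodes(self) -> np.ndarray:
        return np.unique(self.bfaces)

    def cavity_volume(self, displacement: np.ndarray | None = None) -> float:
        pts = self.nodes if displacement is None else self.nodes + displacement
        return fem.mesh_volume_from_surface(pts, self.bfaces)

    def average_edge(self) -> float:
        p = self.nodes[self.tets]
        pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        d = np.concatenate(
            [np.linalg.norm(p[:, i] - p[:, j], axis=1) for i, j in pairs]
        )
        return float(d.mean())

    def drop_elements(self, elem_mask: np.ndarray) -> None:
        """Remove the masked elements in place and rebuild the boundary.

        Used to discard the occasional boundary sliver that a prescribed
        deformation would invert; node numbering is unchanged.
        """
        keep = ~np.asarray(elem_mask, dtype=bool)
        if self.locator is not None:
            old_to_new = np.full(len(self.tets), -1)
            old_to_new[keep] = np.arange(keep.sum())
            s2t = self.locator._simplex_to_tet
            valid = s2t >= 0
            s2t[valid] = old_to_new[s2t[valid]]
        self.tets = self.tets[keep]
        self.elem_region = self.elem_region[keep]
        self.bfaces, self.bface_owner = fem.boundary_faces(self.tets)
        self.bface_tag = _tag_faces(self.nodes, self.bfaces, self.primitives,
                                    self._tag_tol,
                                    self.elem_region[self.bface_owner])
        self.check_watertight()

    def check_watertight(self) -> None:
        """Every directed boundary edge must be matched by its reverse."""
        e = np.vstack(
            [
                self.bfaces[:, [0, 1]],
                self.bfaces[:, [1, 2]],
                self.bfaces[:, [2, 0]],
            ]
        )
        fwd = {}
        for u, v in e:
            fwd[(u, v)] = fwd.get((u, v), 0) + 1
        for (u, v), n in fwd.items():
            if fwd.get((v, u), 0) != n:
                raise ValueError(
                    f"non-watertight boundary: directed edge {(u, v)} count {n} "
                    f"vs reverse {fwd.get((v, u), 0)}"
                )


class PointLocator:
    """Barycentric interpolation support on the (reference) mesh."""

    def __init__(self, delaunay: Delaunay, simplex_to_tet: np.ndarray,
                 full_to_mesh: np.ndarray, mesh_nodes: np.ndarray):
        self._dela = delaunay
        self._simplex_to_tet = simplex_to_tet
        self._full_to_mesh = full_to_mesh
        self._tree = cKDTree(mesh_nodes)
        self._n_mesh = len(mesh_nodes)

    def weights(self, pts: np.ndarray):
        """Return (node_idx (M,4), w (M,4)) for interpolation of nodal fields.

        Points outside the kept mesh fall back to their nearest mesh node.
        """
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        simp = self._dela.find_simplex(pts)
        node_idx = np.zeros((len(pts), 4), dtype=int)
        w = np.zeros((len(pts), 4))
        ok = simp >= 0
        if ok.any():
            verts = self._dela.simplices[simp[ok]]
            mapped = self._full_to_mesh[verts]
            T = self._dela.transform[simp[ok]]
            bary = np.einsum(
                "ijk,ik->ij", T[:, :3, :], pts[ok] - T[:, 3, :]
            )
            bw = np.concatenate([bary, 1.0 - bary.sum(axis=1, keepdims=True)], axis=1)
            good = (mapped >= 0).all(axis=1)
            rows = np.where(ok)[0]
            node_idx[rows[good]] = mapped[good]
            w[rows[good]] = bw[good]
            ok_mask = np.zeros(len(pts), bool)
            ok_mask[rows[good]] = True
        else:
            ok_mask = np.zeros(len(pts), bool)
        bad = ~ok_mask
        if bad.any():
            _, nearest = self._tree.query(pts[bad])
            node_idx[bad, 0] = nearest
            w[bad, 0] = 1.0
        return node_idx, w

    def interpolate(self, field: np.ndarray, pts: np.ndarray) -> np.ndarray:
        idx, w = self.weights(pts)
        return np.einsum("mk,mk...->m...", w, field[idx])


def _collapse_slivers(nodes: np.ndarray, tets: np.ndarray,
                      prim: HeartPrimitives, h_ref: float,
                      q_min: float = 0.05, max_rounds: int = 8):
    """Merge away sliver tetrahedra by collapsing their shortest edge.

    Slivers (near-zero altitude) have rank-deficient viscous coupling and
    vanishing lumped mass, which destabilizes the flow solve; collapsing
    the short edge removes them while moving nodes by less than the edge
    length.  Surface nodes absorb interior ones so the boundary shape is
    kept.  Returns (nodes, tets, node_map) with node_map mapping old to new
    node ids.
    """
    n0 = len(nodes)
    node_map = np.arange(n0)
    pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    for _ in range(max_rounds):
        p = nodes[tets]
        V = np.abs(fem.tet_volumes(nodes, tets))
        edges = np.stack(
            [np.linalg.norm(p[:, a] - p[:, b], axis=1) for a, b in pairs], axis=1
        )
        me = edges.max(axis=1)
        q = 8.4853 * V / np.maximum(me, 1e-30) ** 3  # 1 for a regular tet
        bad = np.where(q < q_min)[0]
        if len(bad) == 0:
            break
        on_surf = np.abs(prim.sdf(nodes)) < 0.05 * h_ref
        incident: dict[int, list[int]] = {}
        for ei, t in enumerate(tets):
            for x in t:
                incident.setdefault(int(x), []).append(ei)
        merged = np.zeros(len(nodes), dtype=bool)
        target = np.arange(len(nodes))
        progress = False
        for e in bad:
            t = tets[e]
            order = np.argsort(edges[e])
            done = False
            for k in map(int, order):
                a, b = int(t[pairs[k][0]]), int(t[pairs[k][1]])
                if merged[a] or merged[b]:
                    continue
                if on_surf[b] and not on_surf[a]:
                    a, b = b, a
                newpos = (
                    nodes[a]
                    if (on_surf[a] or on_surf[b])
                    else (nodes[a] + nodes[b]) / 2.0
                )
                affected = set(incident.get(a, [])) | set(incident.get(b, []))
                ok = True
                for ei in affected:
                    tt = tets[ei]
                    if a in tt and b in tt:
                        continue  # removed by the collapse
                    ptt = nodes[tt].copy()
                    for j, x in enumerate(tt):
                        if x == a or x == b:
                            ptt[j] = newpos
                    vol = np.dot(
                        np.cross(ptt[1] - ptt[0], ptt[2] - ptt[0]), ptt[3] - ptt[0]
                    ) / 6.0
                    if vol <= 1e-9 * h_ref**3:
                        ok = False
                        break
                if not ok:
                    continue
                nodes[a] = newpos
                target[b] = a
                merged[a] = merged[b] = True
                progress = True
                done = True
                break
            # a bad tet whose every edge collapse would invert a neighbour
            # is left alone this round
        if not progress:
            break
        tets = target[tets]
        keep = (
            (tets[:, 0] != tets[:, 1]) & (tets[:, 0] != tets[:, 2])
            & (tets[:, 0] != tets[:, 3]) & (tets[:, 1] != tets[:, 2])
            & (tets[:, 1] != tets[:, 3]) & (tets[:, 2] != tets[:, 3])
        )
        tets = tets[keep]
        # merges can duplicate an element (two tets collapsing onto the
        # same vertex set); keep a single copy
        key = np.sort(tets, axis=1)
        _, first = np.unique(key, axis=0, return_index=True)
        tets = tets[np.sort(first)]
        node_map = target[node_map]
    used = np.unique(tets)
    renum = np.full(len(nodes), -1)
    renum[used] = np.arange(len(used))
    node_map = renum[node_map]
    return nodes[used], renum[tets], node_map


def _grid_points(lo, hi, h):
    axes = [np.arange(lo[k], hi[k] + h / 2, h) for k in range(3)]
    return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)


def build_mesh(
    prim: HeartPrimitives,
    h: float = 4.5,
    h_fine: float | None = None,
    refine_z: tuple[float, float] = (-12.0, 10.0),
    seed: int = 0,
    dilation: float = 1.0,
    collapse_slivers: bool = False,
    extra_fine: list | None = None,
) -> HeartMesh:
    """Mesh the cavity; optional graded refinement in a slab around the
    valvular plane (where the immersed valves live).

    ``dilation`` scales the primitives (and the slab and mesh sizes) by the
    given similarity factor before meshing, so the dilated scenario is a
    scaled copy of the baseline mesh topology parameters.  ``extra_fine``
    is an optional list of ``(center_xyz, radius, h_local)`` spheres (e.g.
    around a regurgitant orifice) meshed at their own resolution.
    """
    extra_fine = list(extra_fine or [])
    if dilation != 1.0:
        prim = prim.scaled(dilation)
        h = h * dilation
        h_fine = None if h_fine is None else h_fine * dilation
        refine_z = (refine_z[0] * dilation, refine_z[1] * dilation)
        extra_fine = [(np.asarray(c) * dilation, r * dilation, hh * dilation)
                      for c, r, hh in extra_fine]
    rng = np.random.default_rng(seed)
    lo, hi = prim.bbox(margin=2.0)

    def in_slab(pts):
        # valve plane slab plus the whole aortic tube: both the immersed
        # valves and the outflow tract need the finer resolution
        slab = (pts[:, 2] > refine_z[0]) & (pts[:, 2] < refine_z[1])
        tube = prim.sdf_aorta(pts) < 0.3 * h
        return slab | tube

    def in_extra(pts):
        m = np.zeros(len(pts), dtype=bool)
        for c, r, _hh in extra_fine:
            m |= np.linalg.norm(pts - np.asarray(c), axis=1) < r
        return m

    clouds = []
    if h_fine:
        levels = [(h, lambda p: ~in_slab(p) & ~in_extra(p)),
                  (h_fine, lambda p: in_slab(p) & ~in_extra(p))]
    else:
        levels = [(h, lambda p: ~in_extra(p))]
    for c, r, hh in extra_fine:
        c = np.asarray(c)
        levels.append(
            (hh, lambda p, c=c, r=r: np.linalg.norm(p - c, axis=1) < r)
        )
    for hh, selector in levels:
        # body-centered cubic seeding: its Delaunay is the high-quality
        # tetrahedral lattice, so interior elements are never slivers
        g = _grid_points(lo, hi, hh)
        g = np.vstack([g, g + hh / 2.0])
        g = g[selector(g)]
        f = prim.sdf(g)
        interior = g[f < -0.5 * hh]
        interior = interior[prim.junction_ring_distance(interior) > 0.7 * hh]
        near = g[np.abs(f) < 0.75 * hh]
        surf = prim.project(near)
        # tangential jitter breaks coplanar-lattice degeneracy on the flat
        # caps, then one more projection restores the surface
        tang = rng.uniform(-0.12 * hh, 0.12 * hh, surf.shape)
        eps = 1e-3
        grad = np.empty_like(surf)
        for k in range(3):
            dp = np.zeros(3)
            dp[k] = eps
            grad[:, k] = (prim.sdf(surf + dp) - prim.sdf(surf - dp)) / (2 * eps)
        gn = np.linalg.norm(grad, axis=1, keepdims=True)
        gn[gn < 1e-9] = 1.0
        nrm = grad / gn
        tang -= (np.einsum("ij,ij->i", tang, nrm))[:, None] * nrm
        surf = prim.project(surf + tang, iters=3)
        # dedupe projected points on a lattice at ~0.62 h
        key = np.round(surf / (0.62 * hh)).astype(np.int64)
        _, keep = np.unique(key, axis=0, return_index=True)
        surf = surf[np.sort(keep)]
        clouds.append(interior)
        clouds.append(surf)
    pts = np.vstack(clouds)

    dela = Delaunay(pts)
    cent = pts[dela.simplices].mean(axis=1)
    keep = prim.sdf(cent) < 0.0
    vols = np.abs(fem.tet_volumes(pts, dela.simplices))
    hmin = min([h] + ([h_fine] if h_fine else [])
               + [hh for _, _, hh in extra_fine])
    keep &= vols > 1e-4 * hmin**3
    # drop flat slivers whose vertices all lie on the boundary surface: they
    # have (near-)zero thickness and would invert under the wall motion;
    # removing them only re-exposes interior faces as boundary
    on_surf = np.abs(prim.sdf(pts)) < 0.02 * hmin
    for _ in range(2):
        vol_med = np.median(vols[keep])
        flat = (
            keep
            & on_surf[dela.simplices].all(axis=1)
            & (vols < 0.12 * vol_med)
        )
        if not flat.any():
            break
        keep &= ~flat
    tets_full = dela.simplices[keep]
    simplex_to_tet = np.full(len(dela.simplices), -1, dtype=int)
    simplex_to_tet[np.where(keep)[0]] = np.arange(keep.sum())

    used = np.unique(tets_full)
    full_to_mesh = np.full(len(pts), -1, dtype=int)
    full_to_mesh[used] = np.arange(len(used))
    nodes = pts[used]
    tets = full_to_mesh[tets_full]

    sv = fem.tet_volumes(nodes, tets)
    flip = sv < 0
    tets[flip] = tets[flip][:, [0, 1, 3, 2]]

    if collapse_slivers:
        nodes, tets, node_map = _collapse_slivers(nodes, tets, prim, h_fine or h)
        valid = full_to_mesh >= 0
        full_to_mesh[valid] = node_map[full_to_mesh[valid]]

    elem_region = prim.region_label(nodes[tets].mean(axis=1))

    bfaces, bowner = fem.boundary_faces(tets)
    tol = 0.35 * (h_fine or h)
    tag = _tag_faces(nodes, bfaces, prim, tol, elem_region[bowner])

    # simplex->tet bookkeeping is invalidated by the sliver collapse; the
    # locator only needs the node mapping
    simplex_to_tet = np.full(len(dela.simplices), -1, dtype=int)
    locator = PointLocator(dela, simplex_to_tet, full_to_mesh, nodes)
    mesh = HeartMesh(
        nodes=nodes,
        tets=tets,
        elem_region=elem_region,
        bfaces=bfaces,
        bface_tag=tag,
        bface_owner=bowner,
        primitives=prim,
        locator=locator,
        _tag_tol=tol,
    )
    mesh.check_watertight()
    return mesh


def _tag_faces(nodes: np.ndarray, bfaces: np.ndarray, prim: HeartPrimitives,
               tol: float, owner_region: np.ndarray) -> np.ndarray:
    """Outlet tags require both the cut plane and the owning region: the two
    cap planes can sit at similar heights, so the plane test alone is
    ambiguous."""
    fc = nodes[bfaces].mean(axis=1)
    _, normals = fem.face_areas_normals(nodes, bfaces)
    tag = np.full(len(bfaces), TAG_WALL, dtype=int)
    on_sigma1 = (
        (np.abs(fc[:, 2] - prim.sigma1_z) < tol)
        & (owner_region == REGION_ATRIUM)
        & (normals[:, 2] > 0.7)
    )
    rel = fc - np.asarray(prim.aorta_origin)
    s = rel @ prim.aorta_dir
    on_sigma2 = (
        (np.abs(s - prim.aorta_length) < tol)
        & (owner_region == REGION_AORTA)
        & (normals @ prim.aorta_dir > 0.7)
    )
    tag[on_sigma1] = TAG_ATRIAL_OUTLET
    tag[on_sigma2 & ~on_sigma1] = TAG_AORTIC_OUTLET
    return tag
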