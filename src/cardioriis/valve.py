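"""Mitral-valve reconstruction from radial-plane traces and the immersed
valve machinery for the flow solver.

Pipeline (all in mm until an :class:`ImmersedValve` is built, which is SI):

1. :func:`assemble_point_cloud` — order the 18 x 2 half-profiles of 32
   samples into the 1152-row point-cloud matrix, ring-blockable into
   32 rings x 36 points (ring 1 = annulus, ring 32 = free margin).
2. :func:`fit_rings` — periodic cubic smoothing spline per ring, resampled
   at 1000 points: the 32,000-row cloud.
3. :func:`build_surface` — structured ring x azimuth triangulation at a
   uniform target edge length.
4. :func:`attach_to_wall` — harmonic extension of the annulus-to-wall gap
   over the leaflet surface, then warp (guarantees adhesion).
5. :func:`distance_and_delta` — unsigned distance field and the smoothed
   Dirac layer delta(phi) = (1 + cos(pi phi / eps)) / (2 eps) on |phi| <= eps
   used by the RIIS penalty.

The distance is unsigned: the delta layer is even in phi and no other use
of the sign arises in the systolic (always-closed mitral) setting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.interpolate import splev, splprep
from scipy.sparse.linalg import spsolve
from scipy.spatial import cKDTree

from .geometry import TAG_WALL, HeartMesh, HeartPrimitives
from .phantom import ValveTraces
from .proximity import TriangleProximity

__all__ = [
    "ValvePointCloud",
    "ValveSurface",
    "ImmersedValve",
    "assemble_point_cloud",
    "fit_rings",
    "build_surface",
    "attach_to_wall",
    "distance_and_delta",
    "smoothed_delta",
    "make_scenario_valves",
    "aortic_valve_templates",
]

N_SAMPLES = 32
N_PROFILES = 36
N_RESAMPLE = 1000


@dataclass
class ValvePointCloud:
    """Ordered leaflet trace matrix and (optionally) its ring resampling.

    ``raw`` rows are sample-major within each profile, profiles sorted by
    attachment azimuth: row ``p * 32 + j`` is sample ``j`` of profile ``p``.
    """

    raw: np.ndarray  # (1152, 3)
    profile_azimuths_deg: np.ndarray  # (36,)
    resampled: np.ndarray | None = None  # (32, 1000, 3)
    ring_grid: np.ndarray | None = None  # (32, 36, 3) smoothed, profile order
    noise_sigma_mm: float = 0.3

    def __post_init__(self):
        if self.raw.shape != (N_SAMPLES * N_PROFILES, 3):
            raise ValueError(
                f"raw cloud must have {N_SAMPLES * N_PROFILES} rows, "
                f"got {self.raw.shape}"
            )

    @property
    def rings(self) -> np.ndarray:
        """Ring-blocked view: (32 rings, 36 points, 3)."""
        return self.raw.reshape(N_PROFILES, N_SAMPLES, 3).transpose(1, 0, 2)

    @property
    def resampled_matrix(self) -> np.ndarray:
        if self.resampled is None:
            raise ValueError("call fit_rings first")
        return self.resampled.reshape(-1, 3)


def assemble_point_cloud(traces: ValveTraces) -> ValvePointCloud:
    """Order per-plane traces into the 1152 x 3 cloud matrix.

    Each of the 18 radial planes contributes two half-profiles; the 36
    profiles are sorted by annulus attachment azimuth (anterior profile of
    plane alpha at azimuth alpha, posterior at alpha + 180 degrees), which
    makes ring blocks traverse the annulus once in order.
    """
    if traces.anterior.shape != (18, N_SAMPLES, 3):
        raise ValueError("expected 18 planes x 32 samples per leaflet")
    az = np.concatenate([traces.plane_azimuths_deg, traces.plane_azimuths_deg + 180.0])
    profiles = np.concatenate([traces.anterior, traces.posterior], axis=0)
    order = np.argsort(az, kind="stable")
    return ValvePointCloud(
        raw=profiles[order].reshape(-1, 3),
        profile_azimuths_deg=az[order],
        noise_sigma_mm=getattr(traces, "noise_mm", 0.3),
    )


def _fit_one_ring(pts: np.ndarray, s: float):
    """Periodic cubic spline through one ring.

    Returns the curve resampled at 1000 uniform parameters and the smoothed
    positions of the input points themselves (duplicates — the healthy
    coaptation rows — map to their unique representative's position, so the
    profile correspondence of the ring is preserved).
    """
    # collapse exact duplicates (healthy coaptation rows repeat the margin)
    _, first, inverse = np.unique(
        np.round(pts, 9), axis=0, return_index=True, return_inverse=True
    )
    order = np.argsort(first)
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    idx_unique = np.sort(first)
    pts_u = pts[idx_unique]
    if len(pts_u) < 4:
        raise ValueError("degenerate ring: fewer than 4 distinct points")
    centered = pts_u - pts_u.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise ValueError("degenerate ring: collinear points")
    s_eff = s * len(pts_u) / len(pts)
    # periodic fitting expects an explicitly closed sequence (the last
    # input point is treated as the wrap-around copy of the first)
    closed = np.vstack([pts_u, pts_u[:1]])
    tck, u_pts = splprep(closed.T, s=s_eff, per=1, k=3)
    u = np.linspace(0.0, 1.0, N_RESAMPLE, endpoint=False)
    resampled = np.array(splev(u, tck)).T
    smoothed_u = np.array(splev(u_pts[:-1], tck)).T
    # map each original point to its unique representative's smoothed position
    smoothed = smoothed_u[rank[inverse]]
    return resampled, smoothed


def fit_rings(cloud: ValvePointCloud, smoothing: float | None = None) -> ValvePointCloud:
    """Fit each of the 32 rings with a periodic cubic smoothing spline.

    The smoothing target defaults to the expected squared residual of the
    trace noise, ``3 * n_points * sigma^2`` (zero noise means interpolation).
    """
    sigma = cloud.noise_sigma_mm
    s = 3 * N_PROFILES * sigma**2 if smoothing is None else smoothing
    fits = [_fit_one_ring(ring, s) for ring in cloud.rings]
    res = np.stack([f[0] for f in fits])
    grid = np.stack([f[1] for f in fits])
    return ValvePointCloud(
        raw=cloud.raw.copy(),
        profile_azimuths_deg=cloud.profile_azimuths_deg.copy(),
        resampled=res,
        ring_grid=grid,
        noise_sigma_mm=sigma,
    )


def _grid_faces(ns: int, na: int) -> np.ndarray:
    """Triangulation of a ring x azimuth grid closed in azimuth."""
    i = np.arange(ns - 1)[:, None]
    j = np.arange(na)[None, :]
    jp = (j + 1) % na
    v00 = i * na + j
    v01 = i * na + jp
    v10 = (i + 1) * na + j
    v11 = (i + 1) * na + jp
    f1 = np.stack([v00, v01, v11], axis=-1).reshape(-1, 3)
    f2 = np.stack([v00, v11, v10], axis=-1).reshape(-1, 3)
    return np.vstack([f1, f2])


@dataclass
class ValveSurface:
    """Open leaflet surface with an identified annulus boundary ring."""

    vertices: np.ndarray  # (V, 3)
    faces: np.ndarray  # (F, 3)
    annulus_ids: np.ndarray  # indices of annulus boundary vertices

    @classmethod
    def from_grid(cls, grid: np.ndarray) -> "ValveSurface":
        """Structured ring x azimuth grid; ring 0 is the annulus."""
        ns, na = grid.shape[:2]
        return cls(
            vertices=grid.reshape(-1, 3),
            faces=_grid_faces(ns, na),
            annulus_ids=np.arange(na),
        )

    def annulus_vertex_ids(self) -> np.ndarray:
        return self.annulus_ids

    def to_trimesh(self):
        import trimesh

        return trimesh.Trimesh(self.vertices, self.faces, process=False)

    def area(self) -> float:
        v, f = self.vertices, self.faces
        cr = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        return float(np.linalg.norm(cr, axis=1).sum() / 2.0)

    def edge_length_cv(self) -> float:
        v, f = self.vertices, self.faces
        e = np.vstack([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
        e = np.unique(np.sort(e, axis=1), axis=0)
        L = np.linalg.norm(v[e[:, 0]] - v[e[:, 1]], axis=1)
        return float(L.std() / L.mean())

    def scaled(self, factor: float) -> "ValveSurface":
        return ValveSurface(self.vertices * factor, self.faces.copy(),
                            self.annulus_ids.copy())


def build_surface(cloud: ValvePointCloud, target_edge_mm: float = 1.5,
                  remesh: bool = True) -> ValveSurface:
    """Surface mesh of the resampled rings, remeshed to a uniform edge length.

    A preliminary structured ring x azimuth grid is triangulated (azimuthal
    count from the mean ring circumference, ring count from the mean profile
    length), then isotropically remeshed at the target edge; the annulus and
    free-margin boundary polylines are preserved.
    """
    res = cloud.resampled
    if res is None:
        raise ValueError("cloud must be ring-resampled first (fit_rings)")
    if cloud.ring_grid is not None:
        # profile-corresponded grid: rings x profiles; keeps the leaflet
        # sheets and the coaptation seam coherent (margin rings revisit the
        # seam once per leaflet, so azimuth-uniform resampling would twist
        # the connectivity)
        grid = cloud.ring_grid
    else:
        seg = np.linalg.norm(np.diff(res, axis=1, append=res[:, :1]), axis=2)
        circum = seg.sum(axis=1).mean()
        prof_len = np.linalg.norm(np.diff(res, axis=0), axis=2).sum(axis=0).mean()
        n_az = max(8, int(round(circum / target_edge_mm)))
        n_s = max(4, int(round(prof_len / target_edge_mm)) + 1)
        u = np.linspace(0.0, 1.0, n_az, endpoint=False)
        src_u = np.arange(N_RESAMPLE) / N_RESAMPLE
        ring_pts = np.empty((res.shape[0], n_az, 3))
        for r in range(res.shape[0]):
            for k in range(3):
                ring_pts[r, :, k] = np.interp(u, src_u, res[r, :, k], period=1.0)
        s_src = np.linspace(0.0, 1.0, res.shape[0])
        s_tgt = np.linspace(0.0, 1.0, n_s)
        grid = np.empty((n_s, n_az, 3))
        for j in range(n_az):
            for k in range(3):
                grid[:, j, k] = np.interp(s_tgt, s_src, ring_pts[:, j, k])
    surf = ValveSurface.from_grid(grid)
    if cloud.ring_grid is not None:
        # weld coincident free-margin points into a coaptation seam: where
        # the leaflets coapt the membrane becomes one sheet; a prolapse gap
        # stays open
        v, f, ann = surf.vertices, surf.faces, surf.annulus_ids
        key = np.round(v, 6)
        _, uniq_idx, inv = np.unique(key, axis=0, return_index=True,
                                     return_inverse=True)
        v2 = v[uniq_idx]
        f2 = inv[f]
        ok = (f2[:, 0] != f2[:, 1]) & (f2[:, 1] != f2[:, 2]) & (f2[:, 2] != f2[:, 0])
        surf = ValveSurface(v2, f2[ok], np.unique(inv[ann]))
    if remesh:
        from .remesh import remesh_uniform

        ann_pts = surf.vertices[surf.annulus_ids]
        v, f = remesh_uniform(surf.vertices, surf.faces, target_edge_mm)
        tree = cKDTree(ann_pts)
        from .remesh import _boundary_vertices

        bverts = _boundary_vertices(f)
        d, _ = tree.query(v[bverts])
        ann_ids = bverts[d < 0.35 * target_edge_mm]
        surf = ValveSurface(v, f, ann_ids)
    return surf


def _graph_laplacian_solve(surface: ValveSurface, boundary_ids, boundary_vals):
    """Harmonic (umbrella-weight) extension of boundary data over the mesh.

    Positive uniform weights give a discrete maximum principle: every
    interior value is a convex combination of its neighbours, hence bounded
    componentwise by the boundary extremes.
    """
    faces = surface.faces
    n = surface.vertices.shape[0]
    e = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    e = np.unique(np.sort(e, axis=1), axis=0)
    W = sp.coo_matrix(
        (np.ones(2 * len(e)), (np.r_[e[:, 0], e[:, 1]], np.r_[e[:, 1], e[:, 0]])),
        shape=(n, n),
    ).tocsr()
    deg = np.asarray(W.sum(axis=1)).ravel()
    L = sp.diags(deg) - W
    is_b = np.zeros(n, dtype=bool)
    is_b[boundary_ids] = True
    vals = np.zeros((n, 3))
    vals[boundary_ids] = boundary_vals
    free = ~is_b
    if free.sum() == 0:
        return vals
    Lff = L[free][:, free]
    Lfb = L[free][:, is_b]
    sol = np.empty((free.sum(), 3))
    rhs = -Lfb @ vals[is_b]
    for k in range(3):
        sol[:, k] = spsolve(Lff.tocsc(), rhs[:, k])
    vals[free] = sol
    return vals


def attach_to_wall(
    surface: ValveSurface,
    wall_vertices: np.ndarray,
    wall_faces: np.ndarray,
    max_gap_mm: float = 10.0,
) -> ValveSurface:
    """Warp the valve so its annulus adheres to the wall surface.

    The annulus-to-wall gap vectors are harmonically extended over the
    leaflet and applied as a warp; by the discrete maximum principle the
    free margin never moves more than the largest annulus gap.
    """
    prox = TriangleProximity(wall_vertices, wall_faces)
    ann = surface.annulus_vertex_ids()
    d, cp, _ = prox.query(surface.vertices[ann])
    if d.max() > max_gap_mm:
        raise ValueError(
            f"annulus is {d.max():.2f} mm from the wall "
            f"(threshold {max_gap_mm} mm); check valve placement"
        )
    gap = cp - surface.vertices[ann]
    warp = _graph_laplacian_solve(surface, ann, gap)
    return ValveSurface(surface.vertices + warp, surface.faces.copy(),
                        surface.annulus_ids.copy())


# ---------------------------------------------------------------------------
# RIIS fields
# ---------------------------------------------------------------------------


def smoothed_delta(phi: np.ndarray, eps: float) -> np.ndarray:
    """Cosine-smoothed Dirac layer: (1 + cos(pi phi/eps)) / (2 eps) on
    |phi| <= eps, zero outside.  Unit integral across the layer."""
    phi = np.asarray(phi, dtype=float)
    out = np.zeros_like(phi)
    m = np.abs(phi) <= eps
    out[m] = (1.0 + np.cos(np.pi * phi[m] / eps)) / (2.0 * eps)
    return out


def distance_and_delta(vertices: np.ndarray, faces: np.ndarray,
                       nodes: np.ndarray, eps: float):
    """Unsigned distance phi from solver nodes to the surface, and the
    smoothed delta layer (same units as the inputs)."""
    prox = TriangleProximity(vertices, faces)
    phi, _, _ = prox.query(nodes)
    return phi, smoothed_delta(phi, eps)


@dataclass
class ImmersedValve:
    """A resistive immersed surface for the solver (SI units).

    The mitral valve is always in its closed configuration during systole;
    the aortic valve switches between open/closed template surfaces.  The
    prescribed leaflet velocity is zero.
    """

    name: str
    vertices_m: np.ndarray
    faces: np.ndarray
    eps_m: float = 7.5e-4
    resistance: float = 1.0e4  # kg/(m s)
    state: str = "closed"
    open_vertices_m: np.ndarray | None = None
    open_faces: np.ndarray | None = None

    def __post_init__(self):
        if self.eps_m <= 0 or self.resistance <= 0:
            raise ValueError("eps and R must be positive")

    def active_surface(self):
        """Surface currently penalizing the flow; an open valve with no
        open-template surface penalizes nothing."""
        if self.state == "closed":
            return self.vertices_m, self.faces
        if self.open_vertices_m is None:
            return None
        return self.open_vertices_m, self.open_faces

    def delta_field(self, nodes_m: np.ndarray) -> np.ndarray:
        surf = self.active_surface()
        if surf is None:
            return np.zeros(len(nodes_m))
        _, delta = distance_and_delta(surf[0], surf[1], nodes_m, self.eps_m)
        return delta


def aortic_valve_templates(prim: HeartPrimitives, s_valve_mm: float | None = None,
                           target_edge_mm: float = 1.5):
    """Closed (lumen-spanning disk) and open (wall-hugging sleeve) aortic
    valve template surfaces, in mm, as (vertices, faces) pairs."""
    d = prim.aorta_dir
    if s_valve_mm is None:
        # far enough up the root that the valve disk lies fully inside the
        # tube (above the oblique base-plane cut)
        s_valve_mm = 0.28 * prim.aorta_length
    e1 = np.array([d[2], 0.0, -d[0]])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    center = np.asarray(prim.aorta_origin) + s_valve_mm * d
    r = prim.aorta_radius
    n_az = max(12, int(round(2 * np.pi * r / target_edge_mm)))
    n_r = max(3, int(round(r / target_edge_mm)) + 1)
    # closed: slightly domed disk spanning the lumen
    rads = np.linspace(0.0, r, n_r)[1:]
    th = np.linspace(0.0, 2 * np.pi, n_az, endpoint=False)
    Rg, Tg = np.meshgrid(rads, th, indexing="ij")
    pts = (
        center[None, :]
        + (Rg * np.cos(Tg)).ravel()[:, None] * e1[None, :]
        + (Rg * np.sin(Tg)).ravel()[:, None] * e2[None, :]
        + (0.15 * r * (1 - (Rg / r) ** 2)).ravel()[:, None] * d[None, :]
    )
    apex = center + 0.15 * r * d
    verts = np.vstack([apex, pts])
    grid_id = 1 + np.arange(n_r - 1)[:, None] * n_az + np.arange(n_az)[None, :]
    fan = np.stack(
        [np.zeros(n_az, int), grid_id[0], np.roll(grid_id[0], -1)], axis=1
    )
    i = np.arange(n_r - 2)[:, None]
    j = np.arange(n_az)[None, :]
    jp = (j + 1) % n_az
    q1 = np.stack([grid_id[i, j], grid_id[i + 1, j], grid_id[i + 1, jp]], axis=-1)
    q2 = np.stack([grid_id[i, j], grid_id[i + 1, jp], grid_id[i, jp]], axis=-1)
    closed_faces = np.vstack([fan, q1.reshape(-1, 3), q2.reshape(-1, 3)])
    # open: sleeve pressed against (slightly beyond) the wall downstream of
    # the valve plane, so its resistive layer overlaps the no-slip region
    # instead of eating into the lumen at desk-scale layer thicknesses
    s_vals = s_valve_mm + np.linspace(0.0, 8.0, max(4, int(8 / target_edge_mm)))
    Sg, Tg = np.meshgrid(s_vals, th, indexing="ij")
    sleeve_r = r + 0.8
    sleeve = (
        np.asarray(prim.aorta_origin)[None, :]
        + Sg.ravel()[:, None] * d[None, :]
        + sleeve_r * np.cos(Tg).ravel()[:, None] * e1[None, :]
        + sleeve_r * np.sin(Tg).ravel()[:, None] * e2[None, :]
    )
    open_surf = ValveSurface.from_grid(sleeve.reshape(len(s_vals), n_az, 3))
    return (verts, closed_faces), (open_surf.vertices, open_surf.faces)


def reconstruct_mitral(traces: ValveTraces, mesh: HeartMesh,
                       target_edge_mm: float = 1.5) -> ValveSurface:
    """Full trace-to-surface pipeline, attached to the discrete wall."""
    cloud = assemble_point_cloud(traces)
    cloud = fit_rings(cloud)
    surf = build_surface(cloud, target_edge_mm=target_edge_mm)
    wall_faces = mesh.bfaces[mesh.bface_tag == TAG_WALL]
    return attach_to_wall(surf, mesh.nodes, wall_faces)


def make_scenario_valves(
    scenario: str,
    mesh: HeartMesh,
    traces_healthy: ValveTraces | None = None,
    traces_regurgitant: ValveTraces | None = None,
    eps_m: float = 7.5e-4,
    resistance: float = 1.0e4,
    target_edge_mm: float = 1.5,
    aortic_eps_m: float | None = None,
):
    """Mitral and aortic immersed valves for scenario H, R1 or R2.

    H uses the healthy (coapting) mitral valve and starts with the aortic
    valve open; R1 the regurgitant valve at increased heart rate; R2 the
    regurgitant valve with all geometry dilated by 1.25 (the caller passes
    traces already scaled, consistent with the dilated mesh).  The mitral
    valve is always closed; the aortic valve carries both templates.
    """
    if scenario not in ("H", "R1", "R2"):
        raise ValueError(f"unknown scenario {scenario!r}")
    traces = traces_healthy if scenario == "H" else traces_regurgitant
    if traces is None:
        raise ValueError("valve traces for the requested scenario are required")
    surf = reconstruct_mitral(traces, mesh, target_edge_mm=target_edge_mm)
    mitral = ImmersedValve(
        name="mitral",
        vertices_m=surf.vertices * 1e-3,
        faces=surf.faces,
        eps_m=eps_m,
        resistance=resistance,
        state="closed",
    )
    (cv, cf), (ov, of_) = aortic_valve_templates(
        mesh.primitives, target_edge_mm=target_edge_mm
    )
    aortic = ImmersedValve(
        name="aortic",
        vertices_m=cv * 1e-3,
        faces=cf,
        eps_m=aortic_eps_m if aortic_eps_m is not None else eps_m,
        resistance=resistance,
        state="open" if scenario == "H" else "closed",
        open_vertices_m=ov * 1e-3,
        open_faces=of_,
    )
    return mitral, aortic, surf
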