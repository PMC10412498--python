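"""Synthetic left-heart phantom: geometry, systolic motion, rendered image
stacks and mitral-valve leaflet traces, all with known ground truth.

The phantom plays the role of the patient imaging pipeline: it emulates a
short-axis Cine-MRI stack (1 mm in plane, 8 mm across slices), long-axis
single slices, six usable time frames from end diastole (ED) to end systole
(ES), and the radial-plane leaflet tracing protocol (18 planes rotated 10
degrees apart, 32 spline samples per half profile).  Every generated object
has an analytic reference (closed-form volumes, exact surfaces), which is
what makes the downstream pipeline testable without patient data.

Units: mm and seconds throughout this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from . import fem
from .geometry import HeartMesh, HeartPrimitives, build_mesh
from .imaging import VoxelSeries

__all__ = [
    "PhantomSpec",
    "ValveTraces",
    "heart_primitives",
    "generate_geometry",
    "MotionModel",
    "generate_motion",
    "render_image_series",
    "generate_valve_traces",
    "mitral_orifice_area",
]


@dataclass
class PhantomSpec:
    """Parameters of the synthetic study conditions.

    The defaults are the baseline (healthy, H) conditions: 92 mL target
    stroke volume, 0.32 s systole, six frames, undilated geometry.
    """

    vent_axes_mm: tuple[float, float, float] = (24.0, 24.0, 46.0)
    atrium_radius_mm: float = 19.0
    aorta_radius_mm: float = 8.0
    aorta_length_mm: float = 32.0
    target_sv_ml: float = 92.0
    n_frames: int = 6
    t_s: float = 0.32
    dilation: float = 1.0
    valve_kind: str = "healthy"  # "healthy" | "prolapse"
    orifice_area_mm2: float = 0.0
    trace_noise_mm: float = 0.3
    seed: int = 0
    # meshing (numerical resolution, not a physiological condition)
    mesh_h_mm: float = 4.5
    mesh_h_fine_mm: float = 2.4
    # optional local size around a regurgitant orifice (None/0: disabled)
    mesh_h_orifice_mm: float | None = None
    # fixed anatomical sub-parameters
    annulus_radius_mm: float = 11.5
    aorta_tilt_deg: float = 42.0

    def __post_init__(self):
        if self.n_frames < 2:
            raise ValueError("n_frames must be at least 2")
        if self.dilation <= 0:
            raise ValueError("dilation factor must be positive")
        if self.valve_kind not in ("healthy", "prolapse"):
            raise ValueError(f"unknown valve kind {self.valve_kind!r}")
        if self.valve_kind == "healthy" and self.orifice_area_mm2 != 0.0:
            raise ValueError("healthy valve requires zero orifice area")
        if self.valve_kind == "prolapse" and self.orifice_area_mm2 == 0.0:
            self.orifice_area_mm2 = 40.0  # severe regurgitant orifice default


def heart_primitives(spec: PhantomSpec) -> HeartPrimitives:
    """Implicit primitives implied by a phantom spec (undilated)."""
    r_at = spec.atrium_radius_mm
    r_ann = spec.annulus_radius_mm
    if r_ann >= r_at:
        raise ValueError("annulus radius must be smaller than the atrium radius")
    cz = float(np.sqrt(r_at**2 - r_ann**2))
    return HeartPrimitives(
        vent_axes=spec.vent_axes_mm,
        vent_center_z=-8.0 * spec.vent_axes_mm[2] / 46.0,
        atrium_center=(-11.5, 0.0, cz),
        atrium_radius=r_at,
        sigma1_z=cz + 0.58 * r_at,
        aorta_origin=(15.0, 0.0, 0.0),
        aorta_tilt_deg=spec.aorta_tilt_deg,
        aorta_radius=spec.aorta_radius_mm,
        aorta_length=spec.aorta_length_mm,
    )


def generate_geometry(spec: PhantomSpec) -> HeartMesh:
    """Tagged volume mesh (and implicitly its boundary surfaces).

    Dilation scales all coordinates by the spec factor (similarity
    transform), so cavity volume scales with the cube of the factor.  With
    ``mesh_h_orifice_mm`` set, a prolapsed valve adds local refinement
    spheres along its regurgitant slit (resolving the jet core costs
    roughly half again the element count; the desk-scale scenarios leave
    this off and accept a coarsened jet).
    """
    prim = heart_primitives(spec)
    extra = []
    if spec.valve_kind == "prolapse" and spec.mesh_h_orifice_mm:
        from dataclasses import replace

        spec0 = replace(spec, dilation=1.0, trace_noise_mm=0.0)
        tr = generate_valve_traces(spec0)
        gaps = tr.coaptation_gaps()
        for k in np.where(gaps > 1e-9)[0]:
            mid = 0.5 * (tr.anterior[k, -1, :] + tr.posterior[k, -1, :])
            extra.append((mid, 0.5 * gaps[k] + 3.5, spec.mesh_h_orifice_mm))
    mesh = build_mesh(
        prim,
        h=spec.mesh_h_mm,
        h_fine=spec.mesh_h_fine_mm,
        seed=spec.seed,
        dilation=spec.dilation,
        extra_fine=extra,
    )
    return mesh


# ---------------------------------------------------------------------------
# motion
# ---------------------------------------------------------------------------


class MotionModel:
    """Analytic systolic contraction of the ventricle, referenced to end
    systole, elastically extended to the atrium and aorta.

    The ventricular wall (z <= 0, where the taper is identically one) moves
    by ``d(X, t) = a(t) * g(X)`` with ``g = (x, y, gamma z)`` (radial plus
    longitudinal stretch) and the cosine ramp
    ``a(t) = a_max (1 + cos(pi t / T_S)) / 2``, so the last frame (ES) is
    the reference and cavity volume decreases monotonically.  The atrium
    and aortic wall displacement is the elastic extension of the
    ventricular data (with the atrial outlet pinned), mirroring how imaged
    ventricular motion is propagated to the untracked structures; the full
    per-frame field is ``a(t_i)`` times one unit extension solve.  The
    amplitude ``a_max`` is solved so the ED-to-ES cavity volume change
    (including the elastically following walls) equals the target stroke
    volume.

    The analytic taper (``shape``) is what the image renderer uses for the
    moving cavity; it matches the simulated walls exactly on the ventricle.
    """

    GAMMA_LONG = 0.5  # longitudinal-to-radial stretch ratio

    def __init__(self, spec: PhantomSpec, mesh: HeartMesh):
        from .motion import ExtensionOperator
        from .geometry import TAG_ATRIAL_OUTLET

        self.spec = spec
        self.mesh = mesh
        prim = mesh.primitives
        h = spec.mesh_h_mm * spec.dilation
        self.z0 = 0.0625 * prim.sigma1_z
        # the taper reaches zero strictly below the pinned outlet band so
        # prescribed and pinned wall data meet without a kink
        self.z1 = prim.sigma1_z - 1.1 * h
        wall = mesh.wall_nodes
        band = wall[mesh.nodes[wall, 2] > prim.sigma1_z - 0.8 * h]
        self._presc = np.setdiff1d(wall, band)
        pinned = np.union1d(mesh.outlet_nodes(TAG_ATRIAL_OUTLET), band)
        ext = ExtensionOperator(
            mesh.nodes, mesh.tets, prescribed=self._presc, pinned=pinned,
        )
        self.unit_field = ext.extend(self.shape(mesh.nodes[self._presc]))
        self.a_max = self._solve_amplitude()
        self._check_injective()

    def inverting_elements(self, n_checks: int = 17) -> np.ndarray:
        """Elements whose volume becomes non-positive at any amplitude."""
        bad = set()
        for amp in np.linspace(0.0, self.a_max, n_checks):
            v = fem.tet_volumes(self.mesh.nodes + amp * self.unit_field,
                                self.mesh.tets)
            bad.update(np.where(v <= 0)[0].tolist())
        return np.array(sorted(bad), dtype=int)

    def shape(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        lam = self._taper(pts[:, 2])
        g = np.empty_like(pts, dtype=float)
        g[:, 0] = pts[:, 0]
        g[:, 1] = pts[:, 1]
        g[:, 2] = self.GAMMA_LONG * pts[:, 2]
        return lam[:, None] * g

    def _taper(self, z: np.ndarray) -> np.ndarray:
        t = np.clip((z - self.z0) / (self.z1 - self.z0), 0.0, 1.0)
        return np.cos(0.5 * np.pi * t) ** 2

    def amplitude(self, t: np.ndarray | float) -> np.ndarray | float:
        return self.a_max * 0.5 * (1.0 + np.cos(np.pi * np.asarray(t) / self.spec.t_s))

    def _solve_amplitude(self) -> float:
        mesh = self.mesh
        v0 = mesh.cavity_volume()
        target = self.spec.target_sv_ml * 1e3 * self.spec.dilation**3

        def vol_change(a: float) -> float:
            return mesh.cavity_volume(a * self.unit_field) - v0 - target

        return brentq(vol_change, 0.0, 1.5, xtol=1e-10)

    def _check_injective(self) -> None:
        # the map X + a g(X) cannot fold while a ||grad g||_2 < 1 in the domain
        rng = np.random.default_rng(0)
        lo, hi = self.mesh.primitives.bbox()
        x = rng.uniform(lo, hi, (8000, 3))
        x = x[self.mesh.primitives.sdf(x) < 1.0]
        eps = 1e-3
        J = np.empty((len(x), 3, 3))
        for k in range(3):
            dp = np.zeros(3)
            dp[k] = eps
            J[:, :, k] = (self.shape(x + dp) - self.shape(x - dp)) / (2 * eps)
        lip = np.linalg.norm(J, ord=2, axis=(1, 2)).max()
        # a loose sufficient bound: genuine folding; borderline cases are
        # covered exactly by the per-element inversion check on the mesh
        if self.a_max * lip >= 1.8:
            raise ValueError(
                "motion amplitude too large: deformed surface would self-intersect"
            )

    def frame_times(self) -> np.ndarray:
        return np.linspace(0.0, self.spec.t_s, self.spec.n_frames)

    def displacement(self, pts: np.ndarray, t: float) -> np.ndarray:
        return float(self.amplitude(t)) * self.shape(pts)

    def inverse_map(self, pts: np.ndarray, t: float, iters: int = 10) -> np.ndarray:
        """Solve y = X + a g(X) for X by fixed-point iteration."""
        a = float(self.amplitude(t))
        x = np.array(pts, dtype=float)
        for _ in range(iters):
            x = pts - a * self.shape(x)
        return x


def generate_motion(spec: PhantomSpec, mesh: HeartMesh):
    """Per-frame boundary displacement fields referenced to end systole.

    Returns
    -------
    model : MotionModel
    frames : (n_frames, N, 3) array
        Nodal displacement of *all* mesh nodes per frame: analytic on the
        ventricular wall, elastically extended elsewhere (the phantom's
        equivalent of propagating imaged ventricular motion to the atrium
        and aorta before simulation).
    times : (n_frames,) array
    """
    boundary = set(np.unique(mesh.bfaces))
    for _round in range(4):
        model = MotionModel(spec, mesh)
        bad = model.inverting_elements()
        if len(bad) == 0:
            break
        # a handful of boundary slivers can be flattened by the prescribed
        # deformation; they are removed and the motion recomputed
        droppable = np.array(
            [sum(x in boundary for x in mesh.tets[e]) >= 2 for e in bad]
        )
        if not droppable.all() or len(bad) > 12:
            raise ValueError(
                "prescribed motion inverts interior mesh elements: "
                "self-intersecting deformation"
            )
        mask = np.zeros(len(mesh.tets), dtype=bool)
        mask[bad] = True
        mesh.drop_elements(mask)
        boundary = set(np.unique(mesh.bfaces))
    else:
        raise ValueError("mesh repair did not converge under the motion")
    times = model.frame_times()
    frames = np.asarray(model.amplitude(times))[:, None, None] * model.unit_field[None]
    return model, frames, times


# ---------------------------------------------------------------------------
# imaging
# ---------------------------------------------------------------------------


def _indicator(prim: HeartPrimitives, pts: np.ndarray, width: float = 0.15):
    """Sharp-but-smooth cavity indicator (1 inside, 0 outside)."""
    return 0.5 * (1.0 - np.tanh(prim.sdf(pts) / width))


def render_image_series(
    spec: PhantomSpec,
    mesh: HeartMesh,
    model: MotionModel,
    in_plane_mm: float = 1.0,
    slice_mm: float = 8.0,
    n_sax_slices: int = 15,
    n_thick_samples: int = 7,
    frames: np.ndarray | None = None,
):
    """Render the short-axis stack and two long-axis single-slice series.

    The rendering contract: a voxel's value is the through-thickness average
    (``n_thick_samples`` points across the slice thickness) of the cavity
    indicator sampled at the voxel's in-plane center.  Planes outside the
    phantom bounding box are rejected.
    """
    prim = mesh.primitives
    lo, hi = prim.bbox(margin=4.0)
    times = model.frame_times() if frames is None else np.asarray(frames, float)

    # short-axis: slices normal to z, centered on the ventricle long axis
    nx = int(np.ceil((hi[0] - lo[0]) / in_plane_mm))
    ny = int(np.ceil((hi[1] - lo[1]) / in_plane_mm))
    z_lo = lo[2] - 2.0
    z_slices = z_lo + slice_mm * np.arange(n_sax_slices)
    if z_slices[0] > hi[2] or z_slices[-1] < lo[2]:
        raise ValueError("short-axis slice plan outside the phantom bounding box")
    xs = lo[0] + in_plane_mm * (np.arange(nx) + 0.5)
    ys = lo[1] + in_plane_mm * (np.arange(ny) + 0.5)
    off = slice_mm * (np.arange(n_thick_samples) + 0.5) / n_thick_samples - slice_mm / 2

    def render_plane_stack(points_fn, shape, t):
        vals = np.zeros(shape)
        for k, dz in enumerate(off):
            pts = points_fn(dz)
            ref = model.inverse_map(pts, t)
            vals += _indicator(prim, ref).reshape(shape)
        return vals / len(off)

    X, Y = np.meshgrid(xs, ys, indexing="ij")
    sax_frames = []
    for t in times:
        stack = np.zeros((nx, ny, n_sax_slices))
        for k, zc in enumerate(z_slices):
            pts = np.column_stack(
                [np.repeat(X.ravel(), 1), Y.ravel(), np.full(X.size, zc)]
            )
            vals = np.zeros(X.size)
            for dz in off:
                p = pts.copy()
                p[:, 2] += dz
                vals += _indicator(prim, model.inverse_map(p, t))
            stack[:, :, k] = (vals / len(off)).reshape(nx, ny)
        sax_frames.append(stack)
    sax = VoxelSeries(
        values=np.stack(sax_frames),
        spacing=np.array([in_plane_mm, in_plane_mm, slice_mm]),
        origin=np.array([xs[0], ys[0], z_slices[0]]),
        times=times,
    )

    # long-axis: single slices on the two vertical planes y=0 and x=0
    zs = lo[2] + in_plane_mm * (np.arange(int((hi[2] - lo[2]) / in_plane_mm)) + 0.5)
    lax_list = []
    for axis in (1, 0):  # thickness along y, then along x
        shape = (nx, 1, len(zs)) if axis == 1 else (1, ny, len(zs))
        vals_frames = []
        for t in times:
            inplane = xs if axis == 1 else ys
            P, Z = np.meshgrid(inplane, zs, indexing="ij")
            vals = np.zeros(P.size)
            for d in off:
                pts = np.zeros((P.size, 3))
                pts[:, 0 if axis == 1 else 1] = P.ravel()
                pts[:, axis] = d
                pts[:, 2] = Z.ravel()
                vals += _indicator(prim, model.inverse_map(pts, t))
            vals_frames.append((vals / len(off)).reshape(shape))
        spacing = np.ones(3) * in_plane_mm
        spacing[axis] = slice_mm
        origin = np.array([xs[0], ys[0], zs[0]])
        origin[axis] = -0.0
        lax_list.append(
            VoxelSeries(
                values=np.stack(vals_frames),
                spacing=spacing,
                origin=origin,
                times=times,
            )
        )
    return sax, lax_list


# ---------------------------------------------------------------------------
# valve traces
# ---------------------------------------------------------------------------

P2_SECTOR = (60.0, 120.0)  # plane azimuths (deg) whose posterior side is P2
TENT_DEPTH = 6.0  # systolic tenting of the coaptation ring below the annulus
COAPT_REACH = 8.0  # in-plane reach parameter of the coaptation circle
BOW = 1.5  # leaflet belly sag (mm)


@dataclass
class ValveTraces:
    """Radial-plane leaflet traces: 18 planes, 2 half-profiles, 32 samples."""

    plane_azimuths_deg: np.ndarray  # (18,)
    plane_origin: np.ndarray  # (3,) annulus center
    plane_normals: np.ndarray  # (18, 3)
    anterior: np.ndarray  # (18, 32, 3)
    posterior: np.ndarray  # (18, 32, 3)
    valve_kind: str = "healthy"
    noise_mm: float = 0.3

    def coaptation_gaps(self) -> np.ndarray:
        """Distance between the last anterior and posterior point, per plane."""
        return np.linalg.norm(
            self.anterior[:, -1, :] - self.posterior[:, -1, :], axis=1
        )

    def scaled(self, factor: float) -> "ValveTraces":
        return ValveTraces(
            plane_azimuths_deg=self.plane_azimuths_deg.copy(),
            plane_origin=self.plane_origin * factor,
            plane_normals=self.plane_normals.copy(),
            anterior=self.anterior * factor,
            posterior=self.posterior * factor,
            valve_kind=self.valve_kind,
            noise_mm=self.noise_mm * factor,
        )


def _coaptation_point(center: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Closed coaptation ring, one point per radial plane, in that plane.

    ``C(alpha) = center + R cos(alpha) (cos(alpha), sin(alpha), 0) - tent z``
    traces a circle of radius R/2 offset from the annulus center; each point
    lies exactly in the radial plane of azimuth alpha, and the healthy
    anterior and posterior profiles of that plane share it.
    """
    alpha = np.atleast_1d(alpha)
    r = COAPT_REACH * np.cos(alpha)
    pts = np.zeros((len(alpha), 3))
    pts[:, 0] = center[0] + r * np.cos(alpha)
    pts[:, 1] = center[1] + r * np.sin(alpha)
    pts[:, 2] = -TENT_DEPTH
    return pts


def _leaflet_profile(attach: np.ndarray, tip: np.ndarray, n: int) -> np.ndarray:
    """Bowed profile from an annulus attachment point to the coaptation tip."""
    s = np.linspace(0.0, 1.0, n)[:, None]
    base = (1.0 - s) * attach[None, :] + s * tip[None, :]
    base[:, 2] -= BOW * np.sin(np.pi * s[:, 0])
    return base


def generate_valve_traces(spec: PhantomSpec, rng: np.random.Generator | None = None):
    """Synthesize the radial tracing protocol for the requested valve.

    Healthy: the last anterior and posterior points of every plane coincide
    exactly (full closure was imposed during tracing).  Prolapse: the
    posterior profiles of the P2 sector are displaced toward the atrium,
    opening a regurgitant orifice of the spec'd area between the free
    margins.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)
    prim = heart_primitives(spec)
    center = prim.annulus_center
    r_ann = prim.annulus_radius
    n_planes, n_samples = 18, 32
    alphas = np.deg2rad(10.0 * np.arange(n_planes))

    normals = np.column_stack([-np.sin(alphas), np.cos(alphas), np.zeros(n_planes)])
    ant = np.zeros((n_planes, n_samples, 3))
    post = np.zeros((n_planes, n_samples, 3))
    tips = _coaptation_point(center, alphas)
    for k, a in enumerate(alphas):
        attach_a = center + r_ann * np.array([np.cos(a), np.sin(a), 0.0])
        attach_p = center + r_ann * np.array([np.cos(a + np.pi), np.sin(a + np.pi), 0.0])
        ant[k] = _leaflet_profile(attach_a, tips[k], n_samples)
        post[k] = _leaflet_profile(attach_p, tips[k], n_samples)

    if spec.valve_kind == "prolapse":
        deg = np.rad2deg(alphas)
        in_sector = (deg >= P2_SECTOR[0]) & (deg <= P2_SECTOR[1])
        w = np.zeros(n_planes)
        span = P2_SECTOR[1] - P2_SECTOR[0]
        w[in_sector] = np.sin(np.pi * (deg[in_sector] - P2_SECTOR[0]) / span) ** 2
        beta = alphas + np.pi  # posterior attachment azimuth
        out_dir = np.column_stack([np.cos(beta), np.sin(beta), np.zeros(n_planes)])
        offset_dir = 0.8 * out_dir + np.array([0.0, 0.0, 0.6])  # retract + lift

        def apply(scale: float) -> np.ndarray:
            p = post.copy()
            s = np.linspace(0.0, 1.0, n_samples)[None, :, None] ** 2
            p += scale * (w[:, None] * offset_dir)[:, None, :] * s
            return p

        target = spec.orifice_area_mm2

        def area_err(scale: float) -> float:
            return _orifice_area(ant, apply(scale), in_sector) - target

        hi = 0.9 * (r_ann + COAPT_REACH)
        if area_err(hi) < 0.0:
            raise ValueError(
                f"orifice area {target} mm^2 incompatible with leaflet dimensions"
            )
        scale = brentq(area_err, 0.0, hi, xtol=1e-9)
        post = apply(scale)

    if spec.trace_noise_mm > 0:
        ant = ant + rng.normal(0.0, spec.trace_noise_mm, ant.shape)
        post = post + rng.normal(0.0, spec.trace_noise_mm, post.shape)
        if spec.valve_kind == "healthy":
            # coaptation was *imposed* during tracing: last points stay equal
            post[:, -1, :] = ant[:, -1, :]

    traces = ValveTraces(
        plane_azimuths_deg=np.rad2deg(alphas),
        plane_origin=center,
        plane_normals=normals,
        anterior=ant,
        posterior=post,
        valve_kind=spec.valve_kind,
        noise_mm=spec.trace_noise_mm,
    )
    if spec.dilation != 1.0:
        traces = traces.scaled(spec.dilation)
    return traces


def _orifice_area(ant: np.ndarray, post: np.ndarray, in_sector: np.ndarray) -> float:
    """Area of the polygon between the anterior and posterior free margins."""
    idx = np.where(in_sector)[0]
    if len(idx) == 0:
        return 0.0
    lo = max(idx[0] - 1, 0)
    hi = min(idx[-1] + 1, ant.shape[0] - 1)
    sel = np.arange(lo, hi + 1)
    loop = np.vstack([ant[sel, -1, :], post[sel[::-1], -1, :]])
    c = loop.mean(axis=0)
    v = loop - c
    cross = np.cross(v, np.roll(v, -1, axis=0))
    return float(np.linalg.norm(cross.sum(axis=0)) / 2.0)


def mitral_orifice_area(traces: ValveTraces) -> float:
    """Regurgitant orifice area implied by the free-margin gap (mm^2)."""
    gaps = traces.coaptation_gaps()
    in_sector = gaps > 1e-9
    return _orifice_area(traces.anterior, traces.posterior, in_sector)
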