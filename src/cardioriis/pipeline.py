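"""Scenario orchestration: phantom -> valves -> motion -> flow -> indices.

Three virtual scenarios share one moving left-heart phantom:

- H  : healthy coapting mitral valve, heart rate 75 bpm, T_S = 0.32 s,
       aortic valve open from t = 0 (the isovolumic phase cannot be
       simulated with both valves shut and no stress outlet);
- R1 : P2 posterior prolapse with a regurgitant orifice, heart rate 90 bpm
       (T_S = 0.26 s), both valves closed at t = 0;
- R2 : same regurgitant valve, heart rate 75 bpm, whole geometry and
       displacement dilated by 1.25, both valves closed at t = 0.

Each run records flow rates and slice pressures per step, drives the on/off
aortic valve controller, and distills the quantity-of-interest row
(SV/CO/RV/RF, pressure drop, velocity maxima, atrial turbulence ratio, WSS
averages).
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import fem
from .geometry import (REGION_AORTA, REGION_ATRIUM, REGION_VENTRICLE,
                       TAG_ATRIAL_OUTLET, TAG_AORTIC_OUTLET, TAG_WALL)
from .les import LesParams
from .motion import MovingDomain, ale_velocities
from .phantom import PhantomSpec, generate_geometry, generate_motion, generate_valve_traces
from .post import (IndexReport, compute_indices, pressure_drop_mean,
                   timing_features, turbulence_ratio, wall_shear_stress,
                   wss_on_surface)
from .slicing import plane_section
from .solver import (AorticValveController, BoundaryForcing, FlowState,
                     FlowStepper, FluidProperties, RiisTerm)
from .valve import make_scenario_valves, smoothed_delta
from .proximity import TriangleProximity
from . import waveforms

__all__ = ["ScenarioConfig", "ScenarioResult", "run_scenario", "compare_scenarios"]

SCENARIO_DEFAULTS = {
    "H": dict(heart_rate_bpm=75.0, t_s=0.32, dilation=1.0, valve_kind="healthy"),
    "R1": dict(heart_rate_bpm=90.0, t_s=0.26, dilation=1.0, valve_kind="prolapse"),
    # the dilated scenario restores the basal heart rate; its systole length
    # is taken equal to H's (the shared motion protocol implies it)
    "R2": dict(heart_rate_bpm=75.0, t_s=0.32, dilation=1.25, valve_kind="prolapse"),
}


@dataclass
class ScenarioConfig:
    """One scenario run = phantom conditions + numerical resolution."""

    scenario: str = "H"
    heart_rate_bpm: float = 75.0
    t_s: float = 0.32
    dilation: float = 1.0
    valve_kind: str = "healthy"
    seed: int = 0
    target_sv_ml: float = 92.0
    orifice_area_mm2: float = 0.0  # 0 -> phantom default for prolapse
    trace_noise_mm: float = 0.3
    # numerics (desk-scale defaults; see the methods note).  The layer
    # half-thickness must stay below half the regurgitant slit width or the
    # orifice smears shut; blocking of the coapted membrane at that thin
    # layer is maintained by a stronger penalty (leakage ~ eps^2 / R).
    dt: float = 2.8e-3
    mesh_h_mm: float = 6.1
    mesh_h_fine_mm: float = 3.15
    mesh_h_orifice_mm: float | None = None
    riis_resistance: float = 1.0e5
    riis_eps_mm: float | None = None  # None -> max(0.75, 0.42 * h_fine)
    les_C: float = 1.5
    backflow_mode: str = "null-tangential"
    valve_edge_mm: float = 2.0
    out_dir: str | None = None

    @classmethod
    def for_scenario(cls, scenario: str, **overrides) -> "ScenarioConfig":
        if scenario not in SCENARIO_DEFAULTS:
            raise ValueError(f"unknown scenario {scenario!r}")
        kw = dict(SCENARIO_DEFAULTS[scenario])
        kw.update(overrides)
        return cls(scenario=scenario, **kw)

    def validate(self) -> None:
        if self.scenario not in SCENARIO_DEFAULTS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.scenario == "R2" and self.dilation == 1.0:
            raise ValueError("R2 requires the dilated geometry")
        if self.scenario == "H" and self.valve_kind != "healthy":
            raise ValueError("H requires the healthy valve")
        if self.scenario in ("R1", "R2") and self.valve_kind != "prolapse":
            raise ValueError("regurgitant scenarios require the prolapsed valve")

    def phantom_spec(self) -> PhantomSpec:
        return PhantomSpec(
            target_sv_ml=self.target_sv_ml,
            t_s=self.t_s,
            dilation=self.dilation,
            valve_kind=self.valve_kind,
            orifice_area_mm2=self.orifice_area_mm2,
            trace_noise_mm=self.trace_noise_mm,
            seed=self.seed,
            mesh_h_mm=self.mesh_h_mm,
            mesh_h_fine_mm=self.mesh_h_fine_mm,
            mesh_h_orifice_mm=self.mesh_h_orifice_mm,
        )


@dataclass
class ScenarioResult:
    config: ScenarioConfig
    report: IndexReport
    history: pd.DataFrame
    mesh_nodes: int
    mesh_tets: int
    wall_time_s: float

    def save(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.history.to_csv(out / "history.csv", index=False)
        manifest = {
            "config": asdict(self.config),
            "report": self.report.as_dict(),
            "mesh_nodes": self.mesh_nodes,
            "mesh_tets": self.mesh_tets,
            "wall_time_s": self.wall_time_s,
        }
        (out / "report.json").write_text(json.dumps(manifest, indent=2))
        return out


class _MovingValve:
    """An immersed valve advected with the ALE displacement field."""

    def __init__(self, valve, mesh, band_m: float):
        self.valve = valve
        self.band = band_m
        loc = mesh.locator
        self._weights = {}
        for which, verts in (("closed", valve.vertices_m),
                             ("open", valve.open_vertices_m)):
            if verts is None:
                continue
            idx, w = loc.weights(verts * 1e3)  # locator works in mm
            self._weights[which] = (idx, w, verts)

    def current_surface(self, d_m: np.ndarray):
        which = "closed" if self.valve.state == "closed" else "open"
        if which == "open" and "open" not in self._weights:
            return None
        idx, w, verts = self._weights[which]
        disp = np.einsum("mk,mki->mi", w, d_m[idx])
        faces = self.valve.faces if which == "closed" else self.valve.open_faces
        return verts + disp, faces

    def riis_term(self, d_m, nodes_cur, tets) -> RiisTerm | None:
        surf = self.current_surface(d_m)
        if surf is None:
            return None
        verts, faces = surf
        tree = cKDTree(verts)
        eps = self.valve.eps_m
        # point-to-surface >= point-to-nearest-vertex - max triangle edge,
        # so this vertex-tree band cannot miss a layer point
        edge_max = np.linalg.norm(
            verts[faces[:, 0]] - verts[faces[:, 1]], axis=1
        ).max()
        band = eps + 1.05 * edge_max
        n_delta = np.zeros(len(nodes_cur))
        d, _ = tree.query(nodes_cur, distance_upper_bound=band)
        cand = np.where(np.isfinite(d))[0]
        # element-level layer sampling at the centroid and the four face
        # midpoints: a membrane crossing an element between its nodes still
        # contributes the right amount of resistance
        p = nodes_cur[tets]
        cent = p.mean(axis=1)
        dc, _ = tree.query(cent, distance_upper_bound=band + 2e-3)
        candc = np.where(np.isfinite(dc))[0]
        e_delta = np.zeros(len(tets))
        if len(cand) or len(candc):
            prox = TriangleProximity(verts, faces)
            samples = [cent[candc]]
            for drop in range(4):
                keepv = [v for v in range(4) if v != drop]
                samples.append(p[candc][:, keepv, :].mean(axis=1))
            query_pts = np.vstack([nodes_cur[cand]] + samples)
            phi, _, _ = prox.query(query_pts)
            delta_all = smoothed_delta(phi, eps)
            n_delta[cand] = delta_all[: len(cand)]
            rest = delta_all[len(cand):].reshape(5, len(candc))
            e_delta[candc] = rest.mean(axis=0)
        return RiisTerm(delta=n_delta, resistance=self.valve.resistance,
                        eps=eps, delta_elem=e_delta)


def run_scenario(config: ScenarioConfig, progress: bool = False) -> ScenarioResult:
    """Run one scenario end to end and distill the index report."""
    t_start = time.time()
    config.validate()
    spec = config.phantom_spec()
    mesh = generate_geometry(spec)
    model, frames_mm, times = generate_motion(spec, mesh)
    prim = mesh.primitives

    # valve traces are generated in the undilated frame and scaled by the
    # phantom (consistent with dilating geometry and displacement together)
    healthy = regurg = None
    if config.valve_kind == "healthy":
        healthy = generate_valve_traces(spec)
    else:
        regurg = generate_valve_traces(spec)
    # layer half-thickness per valve: the coapted healthy membrane (and the
    # aortic templates) can use a thick, well-integrated layer; the
    # prolapsed valve must stay thinner than half the orifice slit width,
    # which its refinement sphere resolves
    eps_mm = config.riis_eps_mm
    if eps_mm is None:
        if config.valve_kind == "prolapse":
            h_loc = config.mesh_h_orifice_mm or config.mesh_h_fine_mm
            eps_mm = max(0.75, 0.42 * h_loc) * config.dilation
        else:
            eps_mm = max(0.75, 0.7 * config.mesh_h_fine_mm) * config.dilation
    aortic_eps_mm = max(0.75, 0.7 * config.mesh_h_fine_mm) * config.dilation
    mitral, aortic, _surf = make_scenario_valves(
        config.scenario, mesh, traces_healthy=healthy, traces_regurgitant=regurg,
        eps_m=eps_mm * 1e-3, resistance=config.riis_resistance,
        target_edge_mm=config.valve_edge_mm * config.dilation,
        aortic_eps_m=aortic_eps_mm * 1e-3,
    )

    md = MovingDomain(
        mesh=mesh, frame_disp_m=frames_mm * 1e-3, frame_times=times,
        dt=config.dt,
    )
    nodes0 = md.nodes_m
    n = len(nodes0)
    props = FluidProperties()
    les = LesParams(C=config.les_C, delta_m=mesh.average_edge() * 1e-3)
    stepper = FlowStepper(mesh.tets, n, props, les=les)

    p_ao = waveforms.aortic_pressure(config.t_s)
    p_at = waveforms.atrial_pressure(config.t_s, config.valve_kind == "prolapse")
    forcing = BoundaryForcing(p_atrial=p_at, p_aortic=p_ao,
                              backflow_mode=config.backflow_mode)

    s = config.dilation
    axis = prim.aorta_dir
    slice_defs = {
        "ventricle": (np.array([0.0, 0.0, -15.0 * s]) * 1e-3, np.array([0, 0, 1.0]),
                      mesh.elem_region == REGION_VENTRICLE),
        "aorta": ((np.asarray(prim.aorta_origin) + 0.45 * prim.aorta_length * axis)
                  * 1e-3, axis, mesh.elem_region == REGION_AORTA),
        # the LVOT section is the horizontal aortic-root cut just above the
        # base plane: every ejected streamline crosses it inside the tube
        "lvot": (np.array([prim.aorta_origin[0], 0.0, 1.0 * s]) * 1e-3,
                 np.array([0, 0, 1.0]), mesh.elem_region == REGION_AORTA),
        # mitral orifice section: the disk just above the annulus, limited
        # to the orifice region (wall-crease cells outside the annulus
        # radius carry recirculation, not transvalvular flow)
        "mitral": (np.array([prim.annulus_center[0], 0.0, 2.0 * s]) * 1e-3,
                   np.array([0, 0, 1.0]),
                   (mesh.elem_region == REGION_ATRIUM)
                   & (np.hypot(
                       mesh.nodes[mesh.tets].mean(axis=1)[:, 0]
                       - prim.annulus_center[0],
                       mesh.nodes[mesh.tets].mean(axis=1)[:, 1],
                   ) < prim.annulus_radius + 1.5 * s)),
    }
    atrium_mask_e = (mesh.elem_region == REGION_ATRIUM) & (
        mesh.nodes[mesh.tets].mean(axis=1)[:, 2] > 0
    )
    wall_atr_faces = (mesh.bface_tag == TAG_WALL) & (
        mesh.elem_region[mesh.bface_owner] == REGION_ATRIUM
    )
    atr_faces = mesh.bfaces[wall_atr_faces]
    atr_owner = mesh.bface_owner[wall_atr_faces]

    sigma1_faces = mesh.bfaces[mesh.bface_tag == TAG_ATRIAL_OUTLET]
    sigma2_faces = mesh.bfaces[mesh.bface_tag == TAG_AORTIC_OUTLET]
    wall_nodes = mesh.wall_nodes
    sigma1_nodes = mesh.outlet_nodes(TAG_ATRIAL_OUTLET)

    band_m = 2.0 * config.mesh_h_fine_mm * s * 1e-3
    m_mitral = _MovingValve(mitral, mesh, band_m)
    m_aortic = _MovingValve(aortic, mesh, band_m)

    controller = AorticValveController(initially_open=(config.scenario == "H"))

    # mitral valve surface data (reference frame) for valve WSS
    mv_ref_mm = mitral.vertices_m * 1e3
    mv_tm = None
    try:
        import trimesh

        mv_tm = trimesh.Trimesh(mitral.vertices_m, mitral.faces, process=False)
        mv_normals_ref = mv_tm.vertex_normals.copy()
    except Exception:  # pragma: no cover - trimesh is a hard dep in practice
        mv_normals_ref = np.tile([0.0, 0.0, 1.0], (len(mv_ref_mm), 1))

    n_steps = int(round(config.t_s / config.dt))
    state = FlowState.null(n)
    d_old = md.displacement_at(0.0)
    db_old = md.boundary_displacement(0.0)
    rows = []
    for k in range(n_steps):
        t1 = min((k + 1) * config.dt, config.t_s)
        d_new = md.displacement_at(t1)
        db_new = md.boundary_displacement(t1)
        u_ale, u_wall = ale_velocities(d_new, d_old, db_new, db_old, config.dt)
        nodes_cur = md.moved_nodes(d_new)

        riis = []
        for mv in (m_mitral, m_aortic):
            term = mv.riis_term(d_new, nodes_cur, mesh.tets)
            if term is not None:
                riis.append(term)

        tangential = None
        if forcing.backflow_mode == "null-tangential" and config.scenario != "H":
            tangential = (sigma1_nodes, 2)

        state = stepper.step(
            nodes_cur, state, dt=config.dt, u_ale=u_ale,
            dirichlet=[(wall_nodes, u_wall)],
            outlet_faces=[(sigma1_faces, forcing.p_atrial(t1)),
                          (sigma2_faces, forcing.p_aortic(t1))],
            riis=riis, tangential_zero=tangential,
        )

        # probes
        row = {"t": t1}
        for name, (orig, nrm, mask) in slice_defs.items():
            sec = plane_section(nodes_cur, mesh.tets, orig, nrm, elem_mask=mask)
            row[f"Q_{name}"] = sec.flux(nodes_cur, state.u)
            row[f"p_{name}"] = sec.average(nodes_cur, state.p)
            row[f"umax_{name}"] = sec.max_magnitude(state.u)
        # volumetric/surface field probes are smooth in time: sampling them
        # every other step halves their cost without moving the averages
        if k % 2 == 0 or k == n_steps - 1:
            _, vols = fem.tet_gradients(nodes_cur, mesh.tets)
            mu_sgs_e = stepper._last_mu_eff - props.mu
            row["r_atrium"] = turbulence_ratio(mu_sgs_e, vols, atrium_mask_e,
                                               props.mu)
            wss_w, areas_w = wall_shear_stress(
                nodes_cur, mesh.tets, state.u, atr_faces, atr_owner,
                stepper._last_mu_eff,
            )
            row["wss_wall"] = float((wss_w * areas_w).sum() / areas_w.sum())
            mu_eff_mean = props.mu + float(mu_sgs_e.mean())
            wss_mv = wss_on_surface(
                nodes_cur, mesh.tets, mesh.locator, state.u, mv_ref_mm,
                mv_normals_ref, mu_eff_mean,
            )
            row["wss_mv"] = float(wss_mv.mean())
        else:
            row["r_atrium"] = rows[-1]["r_atrium"]
            row["wss_wall"] = rows[-1]["wss_wall"]
            row["wss_mv"] = rows[-1]["wss_mv"]
        row["volume"] = fem.mesh_volume_from_surface(nodes_cur, mesh.bfaces)
        row["aortic_state"] = 1 if controller.state == "open" else 0
        rows.append(row)

        switched = controller.update(
            t1, row["p_ventricle"], row["p_aorta"], row["Q_aorta"]
        )
        if switched:
            aortic.state = controller.state
        d_old, db_old = d_new, db_new
        if progress and (k % 20 == 0 or switched):
            print(f"  t={t1:.3f}s state={controller.state} "
                  f"Q_lvot={row['Q_lvot'] * 1e6:.0f} mL/s")

    hist = pd.DataFrame(rows)
    if controller.t_close is None:
        controller.t_close = config.t_s
    report = _distill(config, hist, controller)
    result = ScenarioResult(
        config=config, report=report, history=hist,
        mesh_nodes=n, mesh_tets=len(mesh.tets),
        wall_time_s=time.time() - t_start,
    )
    if config.out_dir:
        result.save(config.out_dir)
    return result


def _distill(config: ScenarioConfig, hist: pd.DataFrame,
             controller: AorticValveController) -> IndexReport:
    t = hist["t"].to_numpy()
    t_open = controller.t_open if controller.t_open is not None else config.t_s
    t_close = controller.t_close
    q_lvot = hist["Q_lvot"].to_numpy()
    sv, co, rv, rf = compute_indices(
        t, q_lvot, hist["Q_mitral"].to_numpy(), config.heart_rate_bpm
    )
    # healthy-limit bookkeeping: sub-threshold mitral leakage is not
    # clinically regurgitant; threshold = 2% of SV
    if rv < 0.02 * sv and config.valve_kind == "healthy":
        rv, rf = 0.0, 0.0
    t_v1, t_v2, t_dec, flag = timing_features(t, q_lvot, t_close)
    try:
        dp = pressure_drop_mean(
            t, hist["p_ventricle"].to_numpy(), hist["p_aorta"].to_numpy(),
            max(t_open, t[0]), t_close,
        )
    except ValueError:
        dp = float("nan")  # degenerate ejection window (valve never opened)
    return IndexReport(
        scenario=config.scenario,
        dp_mean_mmhg=dp,
        t_open=float(t_open), t_close=float(t_close),
        t_v1=t_v1, t_v2=t_v2, t_dec=t_dec,
        sv_ml=sv, co_l_min=co, rv_ml=rv, rf_pct=rf,
        u_av_max=float(hist["umax_aorta"].max()),
        u_mv_max=float(hist["umax_mitral"].max()),
        r_bar=float(np.trapezoid(hist["r_atrium"], t) / (t[-1] - t[0])),
        wss_mv_mean=float(np.trapezoid(hist["wss_mv"], t) / (t[-1] - t[0])),
        wss_wall_mean=float(np.trapezoid(hist["wss_wall"], t) / (t[-1] - t[0])),
        single_peak_flag=flag,
    )


def compare_scenarios(results: list[ScenarioResult]) -> pd.DataFrame:
    """One row per scenario with the quantity-of-interest column set."""
    if len(results) < 2:
        raise ValueError("need at least two completed runs to compare")
    return pd.DataFrame([r.report.as_dict() for r in results])
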