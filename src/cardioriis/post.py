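"""Hemodynamic postprocessing: flow-rate timing, regurgitation indices,
pressure drops, velocity maxima, atrial turbulence ratio and wall shear
stress.

Index definitions (reported units in parentheses):

- SV (mL): time integral of the LVOT flow rate over systole,
- RV (mL): time integral of the atrium-directed mitral orifice flow,
- CO (L/min): SV x heart rate,
- RF (%): 100 RV / (SV + RV),
- dP_bar (mmHg): time mean of the ventricle-aorta slice pressure drop over
  the ejection window [t_open, t_close],
- U_AV, U_MV (m/s): maxima over time and slice points of |u| at the aortic
  valve plane / through the mitral orifice,
- R_bar (-): time mean of the volume-weighted atrial average of
  mu_sgs / mu,
- WSS_bar (Pa): time means of region-averaged wall shear stress magnitude
  on the mitral valve and the atrial wall.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from . import fem

MMHG = 133.322

__all__ = [
    "IndexReport",
    "timing_features",
    "compute_indices",
    "pressure_drop_mean",
    "turbulence_ratio",
    "wall_shear_stress",
    "wss_histogram",
]


@dataclass
class IndexReport:
    """The per-scenario quantity-of-interest table row."""

    scenario: str
    dp_mean_mmhg: float
    t_open: float
    t_close: float
    t_v1: float | None
    t_v2: float | None
    t_dec: float | None
    sv_ml: float
    co_l_min: float
    rv_ml: float
    rf_pct: float
    u_av_max: float
    u_mv_max: float
    r_bar: float
    wss_mv_mean: float
    wss_wall_mean: float
    single_peak_flag: bool = False

    def __post_init__(self):
        if not (0.0 <= self.rf_pct <= 100.0):
            raise ValueError("regurgitant fraction must lie in [0, 100] %")
        if self.rv_ml < -1e-9:
            raise ValueError("regurgitant volume must be non-negative")
        if self.t_close < self.t_open:
            raise ValueError("aortic valve cannot close before it opens")

    def as_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "dP_mmHg": self.dp_mean_mmhg,
            "tc_minus_to_s": self.t_close - self.t_open,
            "SV_mL": self.sv_ml,
            "CO_L_min": self.co_l_min,
            "RV_mL": self.rv_ml,
            "RF_pct": self.rf_pct,
            "U_AV_m_s": self.u_av_max,
            "U_MV_m_s": self.u_mv_max,
            "R_bar": self.r_bar,
            "WSS_MV_Pa": self.wss_mv_mean,
            "WSS_W_Pa": self.wss_wall_mean,
        }


def timing_features(t: np.ndarray, q_lvot: np.ndarray, t_close: float,
                    min_separation: float | None = None):
    """Peak instants of the LVOT flow and the middle-deceleration time.

    ``t_v1 < t_v2`` are the two most prominent local maxima;
    ``t_dec = (t_v2 + t_close) / 2``.  A monotone or single-peak curve is
    flagged: the single peak is reported as both peaks.
    """
    t = np.asarray(t, float)
    q = np.asarray(q_lvot, float)
    t_span = t[-1] - t[0]
    sep = min_separation if min_separation is not None else 0.05 * t_span
    dist = max(1, int(round(sep / max(np.diff(t).mean(), 1e-12))))
    peaks, props = find_peaks(q, distance=dist, prominence=0.0)
    flag = False
    if len(peaks) == 0:
        flag = True
        k = int(np.argmax(q))
        t_v1 = t_v2 = t[k]
    elif len(peaks) == 1:
        flag = True
        t_v1 = t_v2 = t[peaks[0]]
    else:
        best = np.argsort(props["prominences"])[-2:]
        chosen = np.sort(peaks[best])
        t_v1, t_v2 = t[chosen[0]], t[chosen[1]]
    t_dec = 0.5 * (t_v2 + t_close)
    return t_v1, t_v2, t_dec, flag


def compute_indices(t: np.ndarray, q_lvot: np.ndarray, q_mitral: np.ndarray,
                    heart_rate_bpm: float):
    """SV, CO, RV, RF from the flow-rate series (m^3/s on the SI side).

    Sign conventions: LVOT flow positive toward the aorta (ejection);
    mitral flow positive toward the atrium, so only its positive part is
    regurgitant.  Output in clinical units (mL, L/min, %).
    """
    t = np.asarray(t, float)
    sv_m3 = np.trapezoid(np.asarray(q_lvot, float), t)
    rv_m3 = np.trapezoid(np.clip(np.asarray(q_mitral, float), 0.0, None), t)
    sv_ml = sv_m3 * 1e6
    rv_ml = rv_m3 * 1e6
    if sv_ml < 0:
        raise ValueError(
            f"negative stroke volume ({sv_ml:.1f} mL): sign-convention violation"
        )
    co = sv_ml * heart_rate_bpm / 1000.0  # L/min
    rf = 100.0 * rv_ml / (sv_ml + rv_ml) if (sv_ml + rv_ml) > 0 else 0.0
    return sv_ml, co, rv_ml, rf


def pressure_drop_mean(t: np.ndarray, p_vent: np.ndarray, p_aorta: np.ndarray,
                       t_open: float, t_close: float) -> float:
    """Time mean of the ventricle-aorta slice pressure drop over the
    ejection window, reported in mmHg (inputs Pa)."""
    if t_close <= t_open:
        raise ValueError("ejection window is empty (t_close <= t_open)")
    t = np.asarray(t, float)
    m = (t >= t_open - 1e-12) & (t <= t_close + 1e-12)
    if m.sum() < 2:
        raise ValueError("too few samples in the ejection window")
    dp = np.asarray(p_vent, float)[m] - np.asarray(p_aorta, float)[m]
    tm = t[m]
    return float(np.trapezoid(dp, tm) / (tm[-1] - tm[0]) / MMHG)


def turbulence_ratio(mu_sgs_elem: np.ndarray, elem_vols: np.ndarray,
                     atrium_mask: np.ndarray, mu: float) -> float:
    """Volume-weighted spatial mean of mu_sgs / mu over the atrium."""
    if not np.any(atrium_mask):
        raise ValueError("empty atrium mask")
    v = elem_vols[atrium_mask]
    return float((mu_sgs_elem[atrium_mask] / mu * v).sum() / v.sum())


def wall_shear_stress(nodes: np.ndarray, tets: np.ndarray, u: np.ndarray,
                      faces: np.ndarray, owner: np.ndarray,
                      mu_eff_elem: np.ndarray | float):
    """WSS magnitude per boundary face.

    The traction is evaluated from the owning element's (constant) velocity
    gradient: ``WSS = |(I - n n^T) (2 mu_eff D(u) n)|``; degenerate face
    normals are an error.
    """
    g, _ = fem.tet_gradients(nodes, tets[owner])
    grad_u = np.einsum("fai,faj->fij", u[tets[owner]], g)
    D = 0.5 * (grad_u + np.swapaxes(grad_u, 1, 2))
    areas, normals = fem.face_areas_normals(nodes, faces)
    if np.any(areas <= 0):
        raise ValueError("degenerate boundary face (zero area)")
    mu_f = (np.asarray(mu_eff_elem)[owner]
            if np.ndim(mu_eff_elem) else np.full(len(faces), mu_eff_elem))
    trac = 2.0 * mu_f[:, None] * np.einsum("fij,fj->fi", D, normals)
    tn = np.einsum("fi,fi->f", trac, normals)
    tang = trac - tn[:, None] * normals
    return np.linalg.norm(tang, axis=1), areas


def wss_on_surface(nodes: np.ndarray, tets: np.ndarray, locator,
                   u: np.ndarray, surf_vertices: np.ndarray,
                   surf_normals: np.ndarray, mu_eff: float | np.ndarray):
    """WSS magnitude at immersed-surface vertices from the resolved
    velocity gradient interpolated at each vertex, using the surface's own
    normals."""
    # nodal velocity gradient by volume-weighted element averaging
    g, V = fem.tet_gradients(nodes, tets)
    grad_e = np.einsum("eai,eaj->eij", u[tets], g)
    n = len(nodes)
    grad_n = np.zeros((n, 3, 3))
    wsum = np.zeros(n)
    np.add.at(grad_n, tets.ravel(),
              np.repeat(grad_e * V[:, None, None], 4, axis=0))
    np.add.at(wsum, tets.ravel(), np.repeat(V, 4))
    grad_n /= np.maximum(wsum, 1e-300)[:, None, None]
    grad_v = locator.interpolate(grad_n.reshape(n, 9), surf_vertices)
    grad_v = grad_v.reshape(-1, 3, 3)
    D = 0.5 * (grad_v + np.swapaxes(grad_v, 1, 2))
    mu_v = np.broadcast_to(np.asarray(mu_eff, float), (len(surf_vertices),))
    trac = 2.0 * mu_v[:, None] * np.einsum("fij,fj->fi", D, surf_normals)
    tn = np.einsum("fi,fi->f", trac, surf_normals)
    tang = trac - tn[:, None] * surf_normals
    return np.linalg.norm(tang, axis=1)


def wss_histogram(wss: np.ndarray, edges: np.ndarray):
    """Histogram of WSS magnitudes; the last bin is open-ended, so counts
    sum to the number of sampled points."""
    edges = np.asarray(edges, float)
    counts, _ = np.histogram(wss, bins=np.concatenate([edges, [np.inf]]))
    below = int((wss < edges[0]).sum())
    counts[0] += below
    return counts
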