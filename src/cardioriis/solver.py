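"""Semi-implicit ALE Navier-Stokes with RIIS valve penalties, sigma-model
LES viscosity and SUPG/PSPG-stabilized equal-order (P1-P1) elements.

Momentum balance advanced per step (first-order semi-implicit):

``rho (u^{n+1}-u^n)/dt + rho (u^n - u_ALE).grad u^{n+1}
  - div(2 (mu + mu_sgs(u^n)) D(u^{n+1})) + grad p^{n+1}
  + sum_valves (R/eps)(u^{n+1} - u_Gamma) delta_Gamma = 0``,
``div u^{n+1} = 0``,

with the wall velocity imposed strongly, outlet pressures imposed weakly as
normal tractions, optional null-tangential-velocity backflow control on the
atrial outlet, and a null initial condition.  The convective velocity is
lagged (semi-implicit), the LES viscosity is explicit, the RIIS penalty is
implicit.  One linear solve per step: a Krylov iteration preconditioned by
a periodically refreshed sparse LU of the full system.

Stabilization: element-constant SUPG/PSPG with

``tau = [(2 rho/dt)^2 + (2 rho |w|/h)^2 + (12 mu_eff/h^2)^2
        + (R delta/eps)^2]^{-1/2}``

(h the element diameter, w the convective velocity); the RIIS reaction
enters the tau scaling but the penalty term is left out of the stabilized
residual.  All quantities SI.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import fem
from .les import LesParams, sigma_viscosity

__all__ = [
    "FluidProperties",
    "BoundaryForcing",
    "FlowState",
    "AorticValveController",
    "RiisTerm",
    "FlowStepper",
]


@dataclass
class FluidProperties:
    rho: float = 1.06e3  # kg/m^3
    mu: float = 3.5e-3  # Pa s

    def __post_init__(self):
        if self.rho <= 0 or self.mu <= 0:
            raise ValueError("density and viscosity must be positive")


@dataclass
class BoundaryForcing:
    """Outlet pressure waveforms (Pa, callables of time) and backflow mode."""

    p_atrial: Callable[[float], float]
    p_aortic: Callable[[float], float]
    backflow_mode: str = "null-tangential"  # "null-tangential" | "none"

    def __post_init__(self):
        if self.backflow_mode not in ("null-tangential", "none"):
            raise ValueError(f"unknown backflow mode {self.backflow_mode!r}")


@dataclass
class FlowState:
    u: np.ndarray  # (N,3) m/s
    p: np.ndarray  # (N,)  Pa
    t: float = 0.0
    n: int = 0

    @classmethod
    def null(cls, n_nodes: int) -> "FlowState":
        return cls(u=np.zeros((n_nodes, 3)), p=np.zeros(n_nodes))


@dataclass
class RiisTerm:
    """One immersed surface's contribution: nodal delta field, resistance,
    half-thickness and (zero, here) prescribed surface velocity.

    ``delta_elem`` optionally carries the layer function sampled at element
    centroids; when present the penalty uses the average of the vertex and
    centroid quadratures, which keeps elements cut by the surface between
    nodes from slipping through the layer on coarse meshes.
    """

    delta: np.ndarray  # (N,) 1/m
    resistance: float  # kg/(m s)
    eps: float  # m
    u_gamma: np.ndarray | float = 0.0
    delta_elem: np.ndarray | None = None  # (E,) 1/m


class AorticValveController:
    """On/off aortic valve: instantaneous opening on a positive
    ventricle-aorta pressure jump, closure on reversed aortic-plane flow.

    One opening and one closure per systole; re-opening after closure is
    rejected (and logged) under the single-cycle contract.
    """

    def __init__(self, initially_open: bool, q_developed: float = 5e-6):
        self.state = "open" if initially_open else "closed"
        self.t_open: float | None = 0.0 if initially_open else None
        self.t_close: float | None = None
        self.rejected_reopen = False
        self.q_developed = q_developed  # m^3/s; ejection considered started
        self._q_max = 0.0

    def update(self, t: float, p_ventricle: float, p_aorta: float,
               q_aortic: float) -> bool:
        """Advance the on/off logic; returns True when the state switched."""
        if self.state == "closed" and self.t_close is None:
            if p_ventricle - p_aorta > 0.0:
                self.state = "open"
                self.t_open = t
                return True
        elif self.state == "open":
            self._q_max = max(self._q_max, q_aortic)
            # closure only once forward ejection has developed, so the
            # startup transient cannot shut the valve spuriously
            if (q_aortic < 0.0 and t > (self.t_open or 0.0)
                    and self._q_max > self.q_developed):
                self.state = "closed"
                self.t_close = t
                return True
        elif self.state == "closed" and p_ventricle - p_aorta > 0.0:
            self.rejected_reopen = True
        return False


class FlowStepper:
    """Assembles and advances the stabilized system on a (possibly moving)
    tetrahedral mesh with fixed topology."""

    def __init__(self, tets: np.ndarray, n_nodes: int, props: FluidProperties,
                 les: LesParams | None = None, refactor_every: int = 8,
                 krylov_tol: float = 1e-8):
        self.tets = np.asarray(tets)
        self.n = int(n_nodes)
        self.props = props
        self.les = les
        self.refactor_every = refactor_every
        self.krylov_tol = krylov_tol
        self._lu = None
        self._steps_since_factor = 0
        E = len(self.tets)
        n = self.n
        # fixed COO pattern: 9 uu blocks, 3 up, 3 pu, 1 pp, plus diagonal
        a_idx = self.tets[:, :, None]  # (E,4,1)
        b_idx = self.tets[:, None, :]  # (E,1,4)
        rows, cols = [], []
        for i in range(3):
            for j in range(3):
                rows.append(np.broadcast_to(a_idx + i * n, (E, 4, 4)).ravel())
                cols.append(np.broadcast_to(b_idx + j * n, (E, 4, 4)).ravel())
        for i in range(3):  # up
            rows.append(np.broadcast_to(a_idx + i * n, (E, 4, 4)).ravel())
            cols.append(np.broadcast_to(b_idx + 3 * n, (E, 4, 4)).ravel())
        for j in range(3):  # pu
            rows.append(np.broadcast_to(a_idx + 3 * n, (E, 4, 4)).ravel())
            cols.append(np.broadcast_to(b_idx + j * n, (E, 4, 4)).ravel())
        rows.append(np.broadcast_to(a_idx + 3 * n, (E, 4, 4)).ravel())  # pp
        cols.append(np.broadcast_to(b_idx + 3 * n, (E, 4, 4)).ravel())
        diag = np.arange(3 * n)
        rows.append(diag)
        cols.append(diag)
        self._rows = np.concatenate(rows)
        self._cols = np.concatenate(cols)
        self._n_dof = 4 * n
        # precompute the CSR pattern once (entries + full diagonal for the
        # strong-constraint identities); steps scatter values via bincount
        full_diag = np.arange(self._n_dof)
        rows_all = np.concatenate([self._rows, full_diag])
        cols_all = np.concatenate([self._cols, full_diag])
        order = np.lexsort((cols_all, rows_all))
        sr, sc = rows_all[order], cols_all[order]
        new = np.empty(len(sr), dtype=bool)
        new[0] = True
        new[1:] = (sr[1:] != sr[:-1]) | (sc[1:] != sc[:-1])
        pos_sorted = np.cumsum(new) - 1
        scatter = np.empty(len(order), dtype=np.int64)
        scatter[order] = pos_sorted
        self._scat_main = scatter[: len(self._rows)]
        self._scat_diag = scatter[len(self._rows):]
        self._nnz = int(pos_sorted[-1]) + 1
        self._csr_indices = sc[new].astype(np.int32)
        counts = np.bincount(sr[new], minlength=self._n_dof)
        self._csr_indptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int32)

    # -- single step -------------------------------------------------------
    def step(
        self,
        nodes: np.ndarray,
        state: FlowState,
        dt: float | None,
        u_ale: np.ndarray | None = None,
        dirichlet: list[tuple[np.ndarray, np.ndarray]] | None = None,
        outlet_faces: list[tuple[np.ndarray, float]] | None = None,
        riis: list[RiisTerm] | None = None,
        tangential_zero: tuple[np.ndarray, int] | None = None,
        u_conv: np.ndarray | None = None,
    ) -> FlowState:
        """Advance one time step (or one steady Picard sweep if dt is None).

        Parameters
        ----------
        dirichlet : list of (node indices, (M,3) velocity values)
            Strong velocity constraints (the moving wall).
        outlet_faces : list of ((F,3) outward faces, pressure Pa)
            Weak normal-traction outlets.
        tangential_zero : (node indices, normal axis)
            Null-tangential backflow control: both components orthogonal to
            the given axis are constrained to zero on those nodes.
        u_conv : override of the convective velocity (defaults to u^n).
        """
        n, tets = self.n, self.tets
        props = self.props
        if not (np.all(np.isfinite(state.u)) and np.all(np.isfinite(state.p))):
            raise FloatingPointError("non-finite flow state entering step")
        g, V = fem.tet_gradients(nodes, tets)
        h = fem.tet_max_edge(nodes, tets)
        ML = fem.lumped_mass(n, tets, V)

        u_n = state.u
        w = u_n if u_conv is None else u_conv
        if u_ale is not None:
            w = w - u_ale
        w_e = w[tets].mean(axis=1)  # (E,3)
        un_e = u_n[tets].mean(axis=1)

        mu_eff_e = np.full(len(tets), props.mu)
        if self.les is not None:
            grad_u = np.einsum("eai,eaj->eij", u_n[tets], g)
            mu_eff_e = mu_eff_e + sigma_viscosity(grad_u, self.les, props.rho)
        self._last_mu_eff = mu_eff_e

        riis = riis or []
        r_node = np.zeros(n)
        r_cent = np.zeros(len(tets))
        for term in riis:
            coef = term.resistance / term.eps
            if term.delta_elem is not None:
                r_node += 0.5 * coef * term.delta
                r_cent += 0.5 * coef * term.delta_elem
            else:
                r_node += coef * term.delta
        r_e = r_node[tets].mean(axis=1) + r_cent

        inv_dt = 0.0 if dt is None else 1.0 / dt
        wn = np.linalg.norm(w_e, axis=1)
        base = (
            (2.0 * props.rho * wn / h) ** 2
            + (12.0 * mu_eff_e / h**2) ** 2
            + r_e**2
        )
        tau = 1.0 / np.sqrt((2.0 * props.rho * inv_dt) ** 2 + base)
        # PSPG keeps the steady scaling: the transient term would shrink it
        # with dt and re-admit pressure checkerboarding (the small-time-step
        # instability of equal-order pairs)
        tau_p = 1.0 / np.sqrt(base)

        gg = np.einsum("eak,ebk->eab", g, g)
        wg = np.einsum("ek,eak->ea", w_e, g)  # (E,4) w.grad(phi_a)
        vals = []
        V4 = V / 4.0
        for i in range(3):
            for j in range(3):
                blk = mu_eff_e[:, None, None] * V[:, None, None] * (
                    g[:, :, j][:, :, None] * g[:, :, i][:, None, :]
                )
                if i == j:
                    iso = (mu_eff_e * V)[:, None, None] * gg
                    conv = (props.rho * V4)[:, None, None] * np.broadcast_to(
                        wg[:, None, :], gg.shape
                    )
                    supg_m = (
                        (props.rho * inv_dt * tau * V4)[:, None, None]
                        * np.broadcast_to(wg[:, :, None], gg.shape)
                    )
                    supg_c = (props.rho * tau * V)[:, None, None] * (
                        wg[:, :, None] * wg[:, None, :]
                    )
                    blk = blk + iso + conv + supg_m + supg_c
                vals.append(blk.ravel())
        for i in range(3):  # up: -(p, div v) + SUPG pressure
            base = -(V4[:, None, None]) * np.broadcast_to(
                g[:, :, i][:, :, None], gg.shape
            )
            supg = (tau * V)[:, None, None] * (
                wg[:, :, None] * g[:, :, i][:, None, :]
            )
            vals.append((base + supg).ravel())
        for j in range(3):  # pu: (div u, q) + PSPG
            cont = V4[:, None, None] * np.broadcast_to(
                g[:, :, j][:, None, :], gg.shape
            )
            pspg_m = (inv_dt * tau_p * V4)[:, None, None] * np.broadcast_to(
                g[:, :, j][:, :, None], gg.shape
            )
            pspg_c = (tau_p * V)[:, None, None] * (
                g[:, :, j][:, :, None] * wg[:, None, :]
            )
            vals.append((cont + pspg_m + pspg_c).ravel())
        vals.append(((tau_p / props.rho * V)[:, None, None] * gg).ravel())
        riis_diag = ML * r_node
        # skew-symmetrizing convection correction + rho/2 (div w) u.v keeps
        # the lagged, non-solenoidal convective field from producing energy
        div_w = np.einsum("eai,eai->e", w[tets], g)
        skew_diag = np.zeros(n)
        np.add.at(skew_diag, tets.ravel(),
                  np.repeat(0.5 * props.rho * div_w * V / 4.0, 4))
        if np.any(r_cent):
            np.add.at(riis_diag, tets.ravel(), np.repeat(r_cent * V / 4.0, 4))
        diag_vals = np.tile(props.rho * inv_dt * ML + riis_diag + skew_diag, 3)
        vals.append(diag_vals)
        values = np.concatenate(vals)

        rhs = np.zeros(self._n_dof)
        if dt is not None:
            for k in range(3):
                rhs[k * n : (k + 1) * n] = props.rho * inv_dt * ML * u_n[:, k]
            # SUPG/PSPG right-hand sides (element scatter of the u^n/dt term)
            coef = props.rho * inv_dt * tau * V
            for k in range(3):
                contrib = coef[:, None] * wg * un_e[:, k][:, None]
                np.add.at(rhs, tets.ravel() + k * n, contrib.ravel())
            pspg = (inv_dt * tau_p * V)[:, None] * (g * un_e[:, None, :]).sum(axis=2)
            np.add.at(rhs, tets.ravel() + 3 * n, pspg.ravel())
        for term in riis:
            if np.any(np.asarray(term.u_gamma) != 0.0):
                ug = np.broadcast_to(np.asarray(term.u_gamma, float),
                                     (n, 3))
                coef = ML * term.resistance / term.eps * term.delta
                for k in range(3):
                    rhs[k * n : (k + 1) * n] += coef * ug[:, k]
        for faces, p_out in outlet_faces or []:
            areas, normals = fem.face_areas_normals(nodes, faces)
            contrib = -(p_out / 3.0) * areas[:, None] * normals  # per vertex
            for v in range(3):
                for k in range(3):
                    np.add.at(rhs, faces[:, v] + k * n,
                              contrib[:, k])

        # strong velocity constraints
        constrained = np.zeros(self._n_dof, dtype=bool)
        bc_val = np.zeros(self._n_dof)
        for nodes_d, vals_d in dirichlet or []:
            vv = np.broadcast_to(np.asarray(vals_d, float), (len(nodes_d), 3))
            for k in range(3):
                constrained[nodes_d + k * n] = True
                bc_val[nodes_d + k * n] = vv[:, k]
        if tangential_zero is not None:
            t_nodes, axis = tangential_zero
            for k in range(3):
                if k == axis:
                    continue
                free_before = ~constrained[t_nodes + k * n]
                constrained[t_nodes + k * n] = True
                bc_val[t_nodes + k * n] = np.where(
                    free_before, 0.0, bc_val[t_nodes + k * n]
                )

        if not outlet_faces:
            # no natural (traction) boundary anywhere: pin one pressure DOF
            constrained[3 * n] = True
            bc_val[3 * n] = 0.0

        mask = constrained[self._rows]
        values = np.where(mask, 0.0, values)
        data = np.bincount(self._scat_main, weights=values, minlength=self._nnz)
        data[self._scat_diag[constrained]] += 1.0
        A = sp.csr_matrix(
            (data, self._csr_indices, self._csr_indptr),
            shape=(self._n_dof, self._n_dof),
        )
        rhs[constrained] = bc_val[constrained]

        x = self._solve(A, rhs, state)
        if not np.all(np.isfinite(x)):
            raise FloatingPointError("flow solve produced non-finite values")
        u_new = x[: 3 * n].reshape(3, n).T.copy()
        p_new = x[3 * n :].copy()
        return FlowState(u=u_new, p=p_new,
                         t=state.t + (dt or 0.0), n=state.n + 1)

    def _factorize(self, A: sp.csr_matrix):
        # node-interleaved ordering keeps the LU fill low for the coupled
        # 4-field system; the factorization lives in permuted space
        if not hasattr(self, "_perm"):
            n = self.n
            self._perm = (
                np.arange(n)[:, None] + np.array([0, n, 2 * n, 3 * n])[None, :]
            ).ravel()
            self._iperm = np.empty_like(self._perm)
            self._iperm[self._perm] = np.arange(self._n_dof)
        Ap = A[self._perm][:, self._perm].tocsc()
        self._lu = spla.splu(Ap)
        self._steps_since_factor = 0

    def _lu_apply(self, r: np.ndarray) -> np.ndarray:
        return self._lu.solve(r[self._perm])[self._iperm]

    def _solve(self, A: sp.csr_matrix, rhs: np.ndarray, state: FlowState):
        if (self._lu is None
                or self._steps_since_factor >= self.refactor_every
                or getattr(self, "_force_refactor", False)):
            self._force_refactor = False
            self._factorize(A)
            return self._lu_apply(rhs)
        self._steps_since_factor += 1
        M = spla.LinearOperator(A.shape, matvec=self._lu_apply)
        x0 = np.concatenate([state.u.T.ravel(), state.p])
        bnorm = np.linalg.norm(rhs)
        iters = [0]

        def cb(_):
            iters[0] += 1

        x, info = spla.gmres(A, rhs, x0=x0, M=M, rtol=self.krylov_tol,
                             maxiter=40, restart=40, callback=cb,
                             callback_type="pr_norm")
        res = np.linalg.norm(A @ x - rhs)
        if info != 0 or (bnorm > 0 and res / bnorm > 1e-6):
            self._factorize(A)
            x = self._lu_apply(rhs)
        elif iters[0] > 16:
            # the preconditioner has drifted; refresh before the next step
            self._force_refactor = True
        return x

    # -- steady convenience (verification cases) ----------------------------
    def solve_steady(self, nodes, dirichlet=None, outlet_faces=None,
                     riis=None, n_picard: int = 4) -> FlowState:
        """Steady solve by Picard iteration on the convective velocity."""
        state = FlowState.null(self.n)
        for _ in range(n_picard):
            state = self.step(
                nodes, state, dt=None, dirichlet=dirichlet,
                outlet_faces=outlet_faces, riis=riis, u_conv=state.u,
            )
        return state
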