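"""Moving-domain machinery: time interpolation of the frame displacements,
elastic extension of boundary motion into the volume, and ALE velocities.

The reference configuration is the end-systolic (ES) mesh.  Per time step:

1. interpolate the imaged boundary displacement d_MRI(x, t) (cubic spline
   through the frames, which all reference ES, so the last frame is zero),
2. extend it into the volume by a linear elastostatic solve
   ``-div(2 mu_ext grad_s d + lambda_ext div d I) = 0`` with d = d_MRI on
   the wall, d = 0 on the atrial outlet (kept fixed) and zero traction on
   the aortic outlet (free to follow the rest of the geometry),
3. form the domain (ALE) velocity and wall velocity as backward
   differences of consecutive displacements.

SI units (meters, seconds) throughout: this module sits at the solver
boundary, and the phantom's mm fields are converted on construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.interpolate import CubicSpline
from scipy.sparse.linalg import splu

from . import fem
from .geometry import HeartMesh, TAG_ATRIAL_OUTLET

__all__ = ["ExtensionOperator", "MovingDomain", "interp_displacement",
           "ale_velocities"]


class ExtensionOperator:
    """Factorized linear-elastostatic extension of boundary displacement.

    ``-div(2 mu_ext grad_s d + lambda_ext div d I) = 0`` with Dirichlet data
    on the prescribed node set, zero displacement on the pinned set, and
    natural (zero traction) conditions elsewhere.  Unit-agnostic (the
    operator is homogeneous); factorized once per mesh.
    """

    def __init__(self, nodes: np.ndarray, tets: np.ndarray,
                 prescribed: np.ndarray, pinned: np.ndarray,
                 mu_ext: float = 0.4, lambda_ext: float = 0.4):
        n = len(nodes)
        fixed = np.zeros(n, dtype=bool)
        fixed[prescribed] = True
        fixed[pinned] = True
        self.prescribed = np.asarray(prescribed)
        self.pinned = np.asarray(pinned)
        self._fixed = fixed
        self._n = n
        K = fem.elasticity_matrix(nodes, tets, mu_ext, lambda_ext)
        dof_fixed = np.concatenate([np.where(fixed)[0] + k * n for k in range(3)])
        dof_free = np.concatenate([np.where(~fixed)[0] + k * n for k in range(3)])
        self._dof_fixed = dof_fixed
        self._dof_free = dof_free
        if len(dof_free) == 0:
            raise ValueError("no free DOFs: extension is trivial/misconfigured")
        Kff = K[dof_free][:, dof_free]
        self._lu = splu(Kff.tocsc())
        self._Kfb = K[dof_free][:, dof_fixed]
        self._K = K

    def extend(self, prescribed_disp: np.ndarray) -> np.ndarray:
        """Full nodal field (N, 3) from data on the prescribed nodes."""
        if not np.all(np.isfinite(prescribed_disp)):
            raise ValueError("boundary displacement contains non-finite values")
        n = self._n
        d = np.zeros((n, 3))
        d[self.prescribed] = prescribed_disp
        x = np.zeros(3 * n)
        for k in range(3):
            x[k * n : (k + 1) * n] = d[:, k]
        rhs = -(self._Kfb @ x[self._dof_fixed])
        x[self._dof_free] = self._lu.solve(rhs)
        return x.reshape(3, n).T

    def residual(self, full_disp: np.ndarray) -> float:
        """Relative residual of the free equations at a given field."""
        x = full_disp.T.ravel()
        r = (self._K @ x)[self._dof_free]
        scale = np.abs(self._K[self._dof_free][:, self._dof_fixed]
                       @ x[self._dof_fixed]).max()
        return float(np.abs(r).max() / max(scale, 1e-300))


def interp_displacement(spline: CubicSpline, t: float, t_end: float) -> np.ndarray:
    """Boundary displacement at time t from the frame spline.

    The spline passes through every frame and is C^1 (componentwise cubic);
    times outside [0, t_end] are a hard error.
    """
    if t < -1e-12 or t > t_end + 1e-12:
        raise ValueError(f"time {t} outside the systolic window [0, {t_end}]")
    return spline(np.clip(t, 0.0, t_end))


def ale_velocities(d_new: np.ndarray, d_old: np.ndarray,
                   db_new: np.ndarray, db_old: np.ndarray, dt: float):
    """Backward-difference domain and wall velocities.

    ``u_ALE = (d^{n+1} - d^n) / dt`` on all nodes and
    ``u_wall = (d_MRI^{n+1} - d_MRI^n) / dt`` on the prescribed boundary.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    return (d_new - d_old) / dt, (db_new - db_old) / dt


@dataclass
class MovingDomain:
    """ES-referenced volume mesh with frame displacements and the elastic
    extension operator (factorized once; topology is fixed)."""

    mesh: HeartMesh  # coordinates in mm (geometry side)
    frame_disp_m: np.ndarray  # (n_frames, N, 3) boundary rows are prescribed
    frame_times: np.ndarray  # (n_frames,)
    mu_ext: float = 0.4  # Pa
    lambda_ext: float = 0.4  # Pa
    dt: float = 2.5e-4  # s
    spline_bc: str = "clamped"  # systole starts and ends at rest

    def __post_init__(self):
        self.nodes_m = self.mesh.nodes * 1e-3
        n = len(self.nodes_m)
        if not np.allclose(self.frame_disp_m[-1], 0.0):
            raise ValueError("last frame (end systole) must have zero displacement")
        self.t_end = float(self.frame_times[-1])
        self.wall = self.mesh.wall_nodes
        self.sigma1 = self.mesh.outlet_nodes(TAG_ATRIAL_OUTLET)
        self._spline = CubicSpline(
            self.frame_times, self.frame_disp_m[:, self.wall, :],
            axis=0, bc_type=self.spline_bc,
        )
        # constrained DOFs: wall (prescribed) + atrial outlet (zero);
        # Sigma2 is traction-free (natural)
        self._ext = ExtensionOperator(
            self.nodes_m, self.mesh.tets, prescribed=self.wall,
            pinned=self.sigma1, mu_ext=self.mu_ext, lambda_ext=self.lambda_ext,
        )

    def boundary_displacement(self, t: float) -> np.ndarray:
        """Prescribed displacement on the wall nodes at time t (m)."""
        return interp_displacement(self._spline, t, self.t_end)

    def extend_harmonic(self, wall_disp_m: np.ndarray) -> np.ndarray:
        """Elastic extension of boundary data into the volume.

        Dirichlet: wall = given data, atrial outlet = 0; aortic outlet free.
        Returns the full nodal displacement field (N, 3), solved to direct-
        solver accuracy.
        """
        return self._ext.extend(wall_disp_m)

    def displacement_at(self, t: float) -> np.ndarray:
        """Convenience: boundary interpolation followed by the extension."""
        return self.extend_harmonic(self.boundary_displacement(t))

    def moved_nodes(self, d_m: np.ndarray) -> np.ndarray:
        return self.nodes_m + d_m

    def min_cell_volume(self, d_m: np.ndarray) -> float:
        return float(fem.tet_volumes(self.moved_nodes(d_m), self.mesh.tets).min())
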