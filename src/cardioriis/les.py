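"""Sigma-model LES subgrid viscosity.

``mu_sgs = rho C Delta^2 sigma3 (sigma1 - sigma2)(sigma2 - sigma3) / sigma1^2``
with ``sigma1 >= sigma2 >= sigma3`` the singular values of the velocity
gradient.  The differential operator vanishes for the canonical laminar
flows: pure shear (sigma2 = sigma3 = 0), solid rotation (sigma3 = 0),
axisymmetric and isotropic expansion — which is why it is suited to
wall-bounded transitional flows like the systolic ventricle and atrium.

The filter width Delta is a single global constant per run (the average
mesh edge), and the model constant C defaults to 1.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LesParams", "sigma_viscosity"]


@dataclass
class LesParams:
    C: float = 1.5
    delta_m: float | None = None  # filter width (m); default: average mesh edge

    def __post_init__(self):
        if self.C <= 0:
            raise ValueError("model constant C must be positive")
        if self.delta_m is not None and self.delta_m <= 0:
            raise ValueError("filter width must be positive")


def sigma_viscosity(grad_u: np.ndarray, params: LesParams, rho: float,
                    delta_m: float | None = None) -> np.ndarray:
    """Subgrid viscosity per cell from the (cellwise) velocity gradient.

    ``grad_u`` is (..., 3, 3) with entries du_i/dx_j.  Cells with a zero
    gradient (sigma1 = 0) return exactly zero: the formula's singularity
    there is removable and the physical limit is no subgrid activity.
    """
    delta = delta_m if delta_m is not None else params.delta_m
    if delta is None:
        raise ValueError("filter width required (set LesParams.delta_m)")
    g = np.asarray(grad_u, dtype=float)
    if not np.all(np.isfinite(g)):
        raise ValueError("velocity gradient contains non-finite values")
    sv = np.linalg.svd(g, compute_uv=False)  # descending
    s1, s2, s3 = sv[..., 0], sv[..., 1], sv[..., 2]
    out = np.zeros_like(s1)
    nz = s1 > 0
    # ratio form avoids underflow of s1^2 for near-zero gradients
    out[nz] = (
        rho * params.C * delta**2
        * (s3[nz] / s1[nz]) * ((s1[nz] - s2[nz]) / s1[nz]) * (s2[nz] - s3[nz])
    )
    return np.maximum(out, 0.0)
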