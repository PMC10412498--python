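"""Linear (P1) tetrahedral finite-element utilities.

Everything downstream — the elastic mesh-extension solve, the stabilized
Navier-Stokes step and the surface postprocessing — is built on the small
vectorized kernels in this module: per-element shape-function gradients,
lumped masses, boundary-face extraction with outward normals, and COO
assembly helpers.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

__all__ = [
    "tet_volumes",
    "tet_gradients",
    "tet_max_edge",
    "boundary_faces",
    "face_areas_normals",
    "lumped_mass",
    "assemble_coo",
    "elasticity_matrix",
    "mesh_volume_from_surface",
]


def tet_volumes(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Signed volumes of tetrahedra (positive for right-handed ordering)."""
    p0, p1, p2, p3 = (nodes[tets[:, i]] for i in range(4))
    return np.einsum("ij,ij->i", np.cross(p1 - p0, p2 - p0), p3 - p0) / 6.0


def tet_gradients(nodes: np.ndarray, tets: np.ndarray):
    """Gradients of the four barycentric shape functions per element.

    Returns
    -------
    grads : (E, 4, 3) array
        ``grads[e, a]`` is the constant gradient of shape function *a* on
        element *e*.
    vols : (E,) array
        Element volumes (absolute value).
    """
    p = nodes[tets]  # (E,4,3)
    # Jacobian columns are edge vectors from vertex 0.
    J = np.stack([p[:, 1] - p[:, 0], p[:, 2] - p[:, 0], p[:, 3] - p[:, 0]], axis=2)
    detJ = np.linalg.det(J)
    vols = np.abs(detJ) / 6.0
    Jinv = np.linalg.inv(J)  # (E,3,3)
    # lambda_i(x) = [Jinv (x - p0)]_i for i=1..3, so grad lambda_i is row i
    # of Jinv; lambda_0 = 1 - sum of the others.
    grads = np.empty((tets.shape[0], 4, 3))
    grads[:, 1:, :] = Jinv
    grads[:, 0, :] = -Jinv.sum(axis=1)
    return grads, vols


def tet_max_edge(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Longest edge (element diameter) per tetrahedron."""
    p = nodes[tets]
    pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    d = np.stack(
        [np.linalg.norm(p[:, a] - p[:, b], axis=1) for a, b in pairs], axis=1
    )
    return d.max(axis=1)


_FACE_LOCAL = np.array([[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]])
# Local faces ordered so the normal points out of the element for a
# positively oriented tet.


def boundary_faces(tets: np.ndarray):
    """Faces belonging to exactly one tetrahedron.

    Returns ``(faces, owner)`` where ``faces`` is (F, 3) with outward
    orientation and ``owner`` the owning element index of each face.
    """
    faces = tets[:, _FACE_LOCAL].reshape(-1, 3)  # (4E,3)
    owner = np.repeat(np.arange(len(tets)), 4)
    key = np.sort(faces, axis=1)
    _, inv, counts = np.unique(
        key, axis=0, return_inverse=True, return_counts=True
    )
    mask = counts[inv] == 1
    return faces[mask], owner[mask]


def face_areas_normals(nodes: np.ndarray, faces: np.ndarray):
    """Areas and unit normals of oriented triangular faces."""
    p0, p1, p2 = (nodes[faces[:, i]] for i in range(3))
    cr = np.cross(p1 - p0, p2 - p0)
    a2 = np.linalg.norm(cr, axis=1)
    areas = a2 / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        normals = cr / a2[:, None]
    normals[a2 == 0] = 0.0
    return areas, normals


def lumped_mass(n_nodes: int, tets: np.ndarray, vols: np.ndarray) -> np.ndarray:
    """Row-sum (lumped) mass vector: V/4 contribution per vertex."""
    m = np.zeros(n_nodes)
    np.add.at(m, tets.ravel(), np.repeat(vols / 4.0, 4))
    return m


def assemble_coo(rows, cols, vals, shape) -> sp.csr_matrix:
    """Assemble a CSR matrix from (possibly duplicated) COO triplets."""
    A = sp.coo_matrix(
        (np.asarray(vals).ravel(), (np.asarray(rows).ravel(), np.asarray(cols).ravel())),
        shape=shape,
    )
    return A.tocsr()


def elasticity_matrix(
    nodes: np.ndarray, tets: np.ndarray, mu: float, lam: float
) -> sp.csr_matrix:
    """Stiffness matrix of linear elastostatics ``-div(2 mu e(d) + lam tr e I)``.

    Degrees of freedom are blocked by component: ``[dx(N), dy(N), dz(N)]``.
    """
    n = len(nodes)
    g, V = tet_gradients(nodes, tets)
    # K[(i,a),(j,b)] = V * ( mu*(g_a.g_b) delta_ij + mu*g_b_i g_a_j + lam*g_a_i g_b_j )
    gg = np.einsum("eak,ebk->eab", g, g)  # (E,4,4)
    rows_all, cols_all, vals_all = [], [], []
    for i in range(3):
        for j in range(3):
            ga_i = g[:, :, i][:, :, None]  # varies over row index a
            ga_j = g[:, :, j][:, :, None]
            gb_i = g[:, :, i][:, None, :]  # varies over column index b
            gb_j = g[:, :, j][:, None, :]
            Ke = mu * ga_j * gb_i + lam * ga_i * gb_j
            if i == j:
                Ke = Ke + mu * gg
            Ke = Ke * V[:, None, None]
            rows_all.append(i * n + np.broadcast_to(tets[:, :, None], Ke.shape))
            cols_all.append(j * n + np.broadcast_to(tets[:, None, :], Ke.shape))
            vals_all.append(Ke)
    return assemble_coo(
        np.concatenate([r.ravel() for r in rows_all]),
        np.concatenate([c.ravel() for c in cols_all]),
        np.concatenate([v.ravel() for v in vals_all]),
        (3 * n, 3 * n),
    )


def mesh_volume_from_surface(nodes: np.ndarray, faces: np.ndarray) -> float:
    """Enclosed volume of a closed, outward-oriented triangle surface.

    Divergence theorem: ``V = (1/3) sum x_c . n A`` over the faces.
    """
    p0, p1, p2 = (nodes[faces[:, i]] for i in range(3))
    cr = np.cross(p1 - p0, p2 - p0)  # 2 A n
    xc = (p0 + p1 + p2) / 3.0
    return float(np.einsum("ij,ij->i", xc, cr).sum() / 6.0)
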