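"""Isotropic surface remeshing at a uniform target edge length.

Classic split/collapse/relax iteration: edges longer than 4/3 of the target
are split at their midpoint, edges shorter than 4/5 are collapsed, interior
vertices are relaxed toward their neighbourhood centroid and projected back
onto the reference surface.  Boundary vertices are kept on their boundary
polyline (relaxed along it, never across it), so the annulus and free
margin of a valve keep their shape.
"""

from __future__ import annotations

import numpy as np

from .proximity import TriangleProximity

__all__ = ["remesh_uniform"]


def _edges_faces(faces: np.ndarray):
    e = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    key = np.sort(e, axis=1)
    uniq, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    return uniq, counts


def _boundary_vertices(faces: np.ndarray) -> np.ndarray:
    uniq, counts = _edges_faces(faces)
    return np.unique(uniq[counts == 1])


def _split_long(verts, faces, lmax):
    """Conforming subdivision: every edge longer than lmax is split in all
    faces that share it (no hanging nodes)."""
    V = np.asarray(verts, dtype=float)
    uniq, _ = _edges_faces(faces)
    L = np.linalg.norm(V[uniq[:, 0]] - V[uniq[:, 1]], axis=1)
    to_split = uniq[L > lmax]
    if len(to_split) == 0:
        return V, np.asarray(faces, dtype=int)
    mid_of = {}
    new_verts = [V]
    next_id = len(V)
    mids = (V[to_split[:, 0]] + V[to_split[:, 1]]) / 2.0
    for (a, b), m in zip(to_split, mids):
        mid_of[(int(a), int(b))] = next_id
        next_id += 1
    new_verts.append(mids)
    Vout = np.vstack(new_verts)

    def mid(a, b):
        return mid_of.get((a, b) if a < b else (b, a))

    out = []
    for f in faces:
        a, b, c = (int(f[0]), int(f[1]), int(f[2]))
        mab, mbc, mca = mid(a, b), mid(b, c), mid(c, a)
        n = sum(x is not None for x in (mab, mbc, mca))
        if n == 0:
            out.append([a, b, c])
        elif n == 3:
            out += [[a, mab, mca], [b, mbc, mab], [c, mca, mbc],
                    [mab, mbc, mca]]
        elif n == 1:
            # rotate so the split edge is (a, b)
            while mab is None:
                a, b, c = b, c, a
                mab, mbc, mca = mbc, mca, mab
            out += [[a, mab, c], [mab, b, c]]
        else:  # n == 2: rotate so the unsplit edge is (c, a)
            while mca is not None:
                a, b, c = b, c, a
                mab, mbc, mca = mbc, mca, mab
            out += [[a, mab, c], [mab, b, mbc], [mab, mbc, c]]
    return Vout, np.asarray(out, dtype=int)


def _collapse_short(verts, faces, lmin, frozen: np.ndarray):
    uniq, counts = _edges_faces(faces)
    L = np.linalg.norm(verts[uniq[:, 0]] - verts[uniq[:, 1]], axis=1)
    order = np.argsort(L)
    neigh = [set() for _ in range(len(verts))]
    for tri in faces:
        for i in range(3):
            a, b = int(tri[i]), int(tri[(i + 1) % 3])
            neigh[a].add(b)
            neigh[b].add(a)
    # opposite vertices of each edge (for the link condition)
    opp = {}
    for tri in faces:
        t = [int(x) for x in tri]
        for i in range(3):
            key = tuple(sorted((t[i], t[(i + 1) % 3])))
            opp.setdefault(key, set()).add(t[(i + 2) % 3])
    target = np.arange(len(verts))
    touched = np.zeros(len(verts), dtype=bool)
    newpos = verts.copy()
    for k in order:
        if L[k] >= lmin:
            break
        a, b = int(uniq[k, 0]), int(uniq[k, 1])
        if touched[a] or touched[b] or frozen[a] or frozen[b]:
            continue
        # link condition: shared neighbours must be exactly the edge's
        # opposite vertices, otherwise the collapse pinches the surface
        if neigh[a] & neigh[b] != opp.get(tuple(sorted((a, b))), set()):
            continue
        target[b] = a
        newpos[a] = (verts[a] + verts[b]) / 2.0
        touched[a] = touched[b] = True
    f = target[faces]
    keep = (f[:, 0] != f[:, 1]) & (f[:, 1] != f[:, 2]) & (f[:, 2] != f[:, 0])
    f = f[keep]
    used = np.unique(f)
    remap = np.full(len(verts), -1)
    remap[used] = np.arange(len(used))
    return newpos[used], remap[f]


def _relax(verts, faces, frozen, prox: TriangleProximity, iters=2):
    n = len(verts)
    for _ in range(iters):
        acc = np.zeros_like(verts)
        cnt = np.zeros(n)
        for i, j in ((0, 1), (1, 2), (2, 0)):
            np.add.at(acc, faces[:, i], verts[faces[:, j]])
            np.add.at(cnt, faces[:, i], 1.0)
            np.add.at(acc, faces[:, j], verts[faces[:, i]])
            np.add.at(cnt, faces[:, j], 1.0)
        cnt[cnt == 0] = 1.0
        cen = acc / cnt[:, None]
        move = ~frozen
        verts = verts.copy()
        verts[move] = cen[move]
        _, cp, _ = prox.query(verts[move])
        verts[move] = cp
    return verts


def _boundary_polyline_segments(verts, faces):
    uniq, counts = _edges_faces(faces)
    be = uniq[counts == 1]
    return verts[be[:, 0]].copy(), verts[be[:, 1]].copy()


def _project_to_polyline(p, seg_a, seg_b):
    """Closest point on a set of segments for each query point."""
    ab = seg_b - seg_a  # (S,3)
    denom = np.einsum("sj,sj->s", ab, ab)
    denom[denom == 0] = 1.0
    out = np.empty_like(p)
    for i, q in enumerate(p):
        t = np.clip(np.einsum("sj,sj->s", q[None] - seg_a, ab) / denom, 0, 1)
        c = seg_a + t[:, None] * ab
        k = np.argmin(np.einsum("sj,sj->s", q[None] - c, q[None] - c))
        out[i] = c[k]
    return out


def remesh_uniform(vertices: np.ndarray, faces: np.ndarray,
                   target_edge: float, iterations: int = 8):
    """Remesh a triangle surface toward a uniform edge length.

    Returns new ``(vertices, faces)``.  Output vertices lie on the input
    surface (projection); boundary vertices stay on the original boundary
    polylines (coarsened along them, never pulled off them).
    """
    prox = TriangleProximity(vertices, faces)
    v, f = np.asarray(vertices, float), np.asarray(faces, int)
    seg_a, seg_b = _boundary_polyline_segments(v, f)
    for _ in range(iterations):
        v, f = _split_long(v, f, 4.0 / 3.0 * target_edge)
        frozen = np.zeros(len(v), dtype=bool)
        frozen[_boundary_vertices(f)] = True
        v, f = _collapse_short(v, f, 0.8 * target_edge, frozen)
        frozen = np.zeros(len(v), dtype=bool)
        bverts = _boundary_vertices(f)
        frozen[bverts] = True
        if len(seg_a) and len(bverts):
            v[bverts] = _project_to_polyline(v[bverts], seg_a, seg_b)
        v = _relax(v, f, frozen, prox)
    return v, f
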