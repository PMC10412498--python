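"""Text-based I/O: legacy-ASCII VTK writers, STL surfaces, trace tables.

Volume meshes go out as VTK UnstructuredGrid with the boundary tags and any
nodal/element fields attached; surfaces as VTK PolyData or STL (via
trimesh).  Valve traces round-trip through a plain CSV with columns
``plane_id, leaflet, sample_idx, x, y, z``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .phantom import ValveTraces

__all__ = ["write_vtk_unstructured", "write_vtk_polydata", "write_stl",
           "traces_to_csv", "traces_from_csv"]


def _header(f, title: str):
    f.write("# vtk DataFile Version 3.0\n")
    f.write(f"{title}\n")
    f.write("ASCII\n")


def _write_points(f, pts: np.ndarray):
    f.write(f"POINTS {len(pts)} double\n")
    np.savetxt(f, pts, fmt="%.10g")


def _write_data(f, name_fields: dict, n: int, kind: str):
    if not name_fields:
        return
    f.write(f"{kind} {n}\n")
    for name, arr in name_fields.items():
        arr = np.asarray(arr)
        if arr.ndim == 1:
            f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            np.savetxt(f, arr, fmt="%.10g")
        else:
            f.write(f"VECTORS {name} double\n")
            np.savetxt(f, arr, fmt="%.10g")


def write_vtk_unstructured(path, nodes, tets, point_data=None, cell_data=None):
    with open(path, "w") as f:
        _header(f, "cardioriis unstructured grid")
        f.write("DATASET UNSTRUCTURED_GRID\n")
        _write_points(f, np.asarray(nodes, float))
        tets = np.asarray(tets)
        f.write(f"CELLS {len(tets)} {5 * len(tets)}\n")
        np.savetxt(f, np.column_stack([np.full(len(tets), 4), tets]), fmt="%d")
        f.write(f"CELL_TYPES {len(tets)}\n")
        np.savetxt(f, np.full(len(tets), 10), fmt="%d")
        _write_data(f, point_data or {}, len(nodes), "POINT_DATA")
        _write_data(f, cell_data or {}, len(tets), "CELL_DATA")


def write_vtk_polydata(path, vertices, faces, point_data=None):
    with open(path, "w") as f:
        _header(f, "cardioriis surface")
        f.write("DATASET POLYDATA\n")
        _write_points(f, np.asarray(vertices, float))
        faces = np.asarray(faces)
        f.write(f"POLYGONS {len(faces)} {4 * len(faces)}\n")
        np.savetxt(f, np.column_stack([np.full(len(faces), 3), faces]), fmt="%d")
        _write_data(f, point_data or {}, len(vertices), "POINT_DATA")


def write_stl(path, vertices, faces):
    import trimesh

    mesh = trimesh.Trimesh(np.asarray(vertices, float), np.asarray(faces),
                           process=False)
    # ascii keeps exported surfaces diffable/inspectable
    data = trimesh.exchange.stl.export_stl_ascii(mesh)
    with open(path, "w") as f:
        f.write(data)


def traces_to_csv(traces: ValveTraces, path) -> None:
    rows = []
    for leaflet, arr in (("anterior", traces.anterior),
                         ("posterior", traces.posterior)):
        for p in range(arr.shape[0]):
            for j in range(arr.shape[1]):
                rows.append((p, leaflet, j, *arr[p, j]))
    pd.DataFrame(rows, columns=["plane_id", "leaflet", "sample_idx",
                                "x", "y", "z"]).to_csv(path, index=False)


def traces_from_csv(path, valve_kind: str = "healthy",
                    noise_mm: float = 0.3) -> ValveTraces:
    df = pd.read_csv(path)
    n_planes = df["plane_id"].nunique()
    n_samples = df["sample_idx"].nunique()

    def block(leaflet):
        sub = df[df.leaflet == leaflet].sort_values(["plane_id", "sample_idx"])
        return sub[["x", "y", "z"]].to_numpy().reshape(n_planes, n_samples, 3)

    ant = block("anterior")
    post = block("posterior")
    alphas = np.deg2rad(10.0 * np.arange(n_planes))
    annulus_mid = 0.5 * (ant[:, 0, :].mean(axis=0) + post[:, 0, :].mean(axis=0))
    return ValveTraces(
        plane_azimuths_deg=10.0 * np.arange(n_planes),
        plane_origin=annulus_mid,
        plane_normals=np.column_stack(
            [-np.sin(alphas), np.cos(alphas), np.zeros(n_planes)]
        ),
        anterior=ant,
        posterior=post,
        valve_kind=valve_kind,
        noise_mm=noise_mm,
    )
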