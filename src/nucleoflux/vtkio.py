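"""Legacy-ASCII VTK unstructured-grid export of meshes and fields.

Writes quadratic tetrahedra (cell type 24) and quadratic triangles
(cell type 22) with per-cell and per-node data arrays, readable by
ParaView and VTK-based tooling.  Kept dependency-free on purpose.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np


def write_vtk(path, mesh, point_data: dict | None = None,
              cell_data: dict | None = None) -> None:
    """Write a mesh plus optional fields to a legacy .vtk file.

    Point data may be scalar (nnodes,) or vector (nnodes, 3); 2D meshes are
    padded with a zero third coordinate.
    """
    path = Path(path)
    coords = np.asarray(mesh.coords, float)
    if coords.shape[1] == 2:
        coords = np.column_stack([coords, np.zeros(len(coords))])
    conn = mesh.conn
    nn = conn.shape[1]
    vtk_type = 24 if nn == 10 else 22

    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\nnucleoflux export\nASCII\n")
        f.write("DATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {len(coords)} double\n")
        np.savetxt(f, coords, fmt="%.9g")
        f.write(f"\nCELLS {len(conn)} {len(conn) * (nn + 1)}\n")
        np.savetxt(f, np.column_stack([np.full(len(conn), nn), conn]), fmt="%d")
        f.write(f"\nCELL_TYPES {len(conn)}\n")
        np.savetxt(f, np.full(len(conn), vtk_type), fmt="%d")

        if point_data:
            f.write(f"\nPOINT_DATA {len(coords)}\n")
            for name, arr in point_data.items():
                arr = np.asarray(arr, float)
                if arr.ndim == 1:
                    f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    np.savetxt(f, arr, fmt="%.9g")
                else:
                    if arr.shape[1] == 2:
                        arr = np.column_stack([arr, np.zeros(len(arr))])
                    f.write(f"VECTORS {name} double\n")
                    np.savetxt(f, arr, fmt="%.9g")
        if cell_data:
            f.write(f"\nCELL_DATA {len(conn)}\n")
            for name, arr in cell_data.items():
                arr = np.asarray(arr, float)
                f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                np.savetxt(f, arr, fmt="%.9g")
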