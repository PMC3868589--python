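"""Minimal legacy-ASCII VTK export for meshes and fields.

Writes unstructured grids with hexahedral cells, cell data (region/layer
labels, scalar fields) and cell/point vector data - enough for visual
inspection of meshes, fiber fields and displacement solutions in ParaView.
"""

from __future__ import annotations

import numpy as np

from .geometry import Mesh

VTK_HEXAHEDRON = 12


def write_vtk(
    path,
    mesh: Mesh,
    point_data: dict | None = None,
    cell_data: dict | None = None,
    displacement: np.ndarray | None = None,
) -> None:
    """Write the mesh (optionally deformed) with labels and extra fields."""
    nodes = mesh.nodes.copy()
    if displacement is not None:
        nodes = nodes + np.asarray(displacement, dtype=float).reshape(-1, 3)
    cells = mesh.elems
    cell_data = dict(cell_data or {})
    cell_data.setdefault("region", mesh.region)
    cell_data.setdefault("layer", mesh.layer)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nlvmech mesh\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {len(nodes)} double\n")
        np.savetxt(fh, nodes, fmt="%.10g")
        fh.write(f"CELLS {len(cells)} {len(cells) * 9}\n")
        np.savetxt(fh, np.column_stack([np.full(len(cells), 8), cells]), fmt="%d")
        fh.write(f"CELL_TYPES {len(cells)}\n")
        np.savetxt(fh, np.full(len(cells), VTK_HEXAHEDRON), fmt="%d")
        if cell_data:
            fh.write(f"CELL_DATA {len(cells)}\n")
            for name, arr in cell_data.items():
                arr = np.asarray(arr)
                if arr.ndim == 1:
                    fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    np.savetxt(fh, arr, fmt="%.10g")
                else:
                    fh.write(f"VECTORS {name} double\n")
                    np.savetxt(fh, arr.reshape(len(cells), -1)[:, :3], fmt="%.10g")
        if point_data:
            fh.write(f"POINT_DATA {len(nodes)}\n")
            for name, arr in point_data.items():
                arr = np.asarray(arr)
                if arr.ndim == 1:
                    fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    np.savetxt(fh, arr, fmt="%.10g")
                else:
                    fh.write(f"VECTORS {name} double\n")
                    np.savetxt(fh, arr, fmt="%.10g")
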