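"""Legacy ASCII VTK output of meshes and field snapshots.

Minimal writers sufficient to inspect runs in ParaView: an unstructured
tetrahedral grid with nodal velocity/pressure, and the tagged boundary
surface (inner_wall=1, outer_wall=2, inlet=3, outlet_1=4, outlet_2=5; the
tag ids are written into the file header comment).
"""

from __future__ import annotations

import numpy as np

from .fem import TAG_NAMES


def write_vtk_volume(path, verts, cells, point_scalars=None, point_vectors=None):
    """Write a tet mesh with optional nodal fields (legacy VTK ASCII)."""
    verts = np.asarray(verts, dtype=float)
    cells = np.asarray(cells, dtype=np.int64)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("pvsflow volume mesh\nASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {len(verts)} double\n")
        np.savetxt(fh, verts, fmt="%.10g")
        fh.write(f"CELLS {len(cells)} {5 * len(cells)}\n")
        np.savetxt(fh, np.column_stack([np.full(len(cells), 4), cells]), fmt="%d")
        fh.write(f"CELL_TYPES {len(cells)}\n")
        np.savetxt(fh, np.full(len(cells), 10), fmt="%d")
        wrote_pd = False
        for name, data in (point_scalars or {}).items():
            if not wrote_pd:
                fh.write(f"POINT_DATA {len(verts)}\n")
                wrote_pd = True
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            np.savetxt(fh, np.asarray(data, dtype=float), fmt="%.10g")
        for name, data in (point_vectors or {}).items():
            if not wrote_pd:
                fh.write(f"POINT_DATA {len(verts)}\n")
                wrote_pd = True
            fh.write(f"VECTORS {name} double\n")
            np.savetxt(fh, np.asarray(data, dtype=float), fmt="%.10g")


def write_vtk_surface(path, verts, faces, face_tags):
    """Write the tagged boundary triangles (legacy VTK ASCII)."""
    verts = np.asarray(verts, dtype=float)
    faces = np.asarray(faces, dtype=np.int64)
    names = ", ".join(f"{k}={v}" for v, k in sorted(
        (v, k) for k, v in TAG_NAMES.items()))
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"pvsflow boundary tags: {names}\nASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {len(verts)} double\n")
        np.savetxt(fh, verts, fmt="%.10g")
        fh.write(f"CELLS {len(faces)} {4 * len(faces)}\n")
        np.savetxt(fh, np.column_stack([np.full(len(faces), 3), faces]), fmt="%d")
        fh.write(f"CELL_TYPES {len(faces)}\n")
        np.savetxt(fh, np.full(len(faces), 5), fmt="%d")
        fh.write(f"CELL_DATA {len(faces)}\n")
        fh.write("SCALARS boundary_tag int 1\nLOOKUP_TABLE default\n")
        np.savetxt(fh, np.asarray(face_tags, dtype=int), fmt="%d")
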