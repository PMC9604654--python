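"""Minimal ASCII VTK XML (.vtu) and STL export.

Writes unstructured grids with point/cell data arrays readable by ParaView —
enough to inspect meshes, fields and isosurfaces without a VTK dependency.
"""

from __future__ import annotations

import io

import numpy as np

from .geometry import TissueMesh
from .metrics import Isosurface

__all__ = ["write_vtu", "export_mesh_vtu", "export_solution_vtu",
           "export_isosurface_vtu", "write_stl"]

VTK_HEXAHEDRON = 12
VTK_TRIANGLE = 5


def _array_txt(a: np.ndarray) -> str:
    buf = io.StringIO()
    np.savetxt(buf, np.atleast_2d(a), fmt="%.9g")
    return buf.getvalue()


def _data_arrays(data: dict) -> str:
    parts = []
    for name, arr in data.items():
        arr = np.asarray(arr)
        ncomp = 1 if arr.ndim == 1 else arr.shape[1]
        parts.append(
            f'<DataArray type="Float64" Name="{name}" '
            f'NumberOfComponents="{ncomp}" format="ascii">\n'
            f"{_array_txt(arr.astype(float))}</DataArray>\n")
    return "".join(parts)


def write_vtu(path, points: np.ndarray, cells: np.ndarray, cell_type: int,
              point_data: dict | None = None,
              cell_data: dict | None = None) -> None:
    """One-cell-type unstructured grid in ASCII VTU format."""
    points = np.asarray(points, dtype=float)
    cells = np.asarray(cells, dtype=np.int64)
    npts, ncells = points.shape[0], cells.shape[0]
    nodes_per_cell = cells.shape[1] if ncells else 0
    offsets = np.arange(1, ncells + 1) * nodes_per_cell
    with open(path, "w") as f:
        f.write('<?xml version="1.0"?>\n'
                '<VTKFile type="UnstructuredGrid" version="0.1" '
                'byte_order="LittleEndian">\n<UnstructuredGrid>\n')
        f.write(f'<Piece NumberOfPoints="{npts}" NumberOfCells="{ncells}">\n')
        f.write('<Points>\n<DataArray type="Float64" NumberOfComponents="3" '
                'format="ascii">\n')
        f.write(_array_txt(points))
        f.write('</DataArray>\n</Points>\n<Cells>\n')
        f.write('<DataArray type="Int64" Name="connectivity" format="ascii">\n')
        if ncells:
            np.savetxt(f, cells, fmt="%d")
        f.write('</DataArray>\n'
                '<DataArray type="Int64" Name="offsets" format="ascii">\n')
        if ncells:
            np.savetxt(f, offsets[:, None], fmt="%d")
        f.write('</DataArray>\n'
                '<DataArray type="UInt8" Name="types" format="ascii">\n')
        if ncells:
            np.savetxt(f, np.full((ncells, 1), cell_type), fmt="%d")
        f.write('</DataArray>\n</Cells>\n')
        f.write('<PointData>\n' + _data_arrays(point_data or {})
                + '</PointData>\n')
        f.write('<CellData>\n' + _data_arrays(cell_data or {})
                + '</CellData>\n')
        f.write('</Piece>\n</UnstructuredGrid>\n</VTKFile>\n')


def export_mesh_vtu(mesh: TissueMesh, path, fibers=None) -> None:
    """Mesh with cell-data "region" and optional "fiber" directions."""
    cell_data = {"region": mesh.element_region.astype(float)}
    if fibers is not None:
        cell_data["fiber"] = fibers.as_element_array(mesh)
    write_vtu(path, mesh.node_coords, mesh.elements, VTK_HEXAHEDRON,
              cell_data=cell_data)


def export_solution_vtu(solution, path) -> None:
    """Field solution: point-data V; cell-data E, E_mag, Q, sigma, region."""
    mesh = solution.mesh
    # mean principal conductivity as a scalar summary of the tensor
    sig = np.trace(solution.sigma_eff, axis1=1, axis2=2) / 3.0
    write_vtu(path, mesh.node_coords, mesh.elements, VTK_HEXAHEDRON,
              point_data={"V": solution.V},
              cell_data={"E": solution.E, "E_mag": solution.e_mag,
                         "Q": solution.Q, "sigma_eff": sig,
                         "region": mesh.element_region.astype(float)})


def export_isosurface_vtu(iso: Isosurface, path) -> None:
    write_vtu(path, iso.vertices, iso.triangles, VTK_TRIANGLE)


def write_stl(iso: Isosurface, path) -> None:
    """ASCII STL of the isosurface triangle soup."""
    with open(path, "w") as f:
        f.write("solid isosurface\n")
        for tri in iso.triangles:
            p = iso.vertices[tri]
            n = np.cross(p[1] - p[0], p[2] - p[0])
            nn = np.linalg.norm(n)
            n = n / nn if nn > 0 else n
            f.write(f"facet normal {n[0]:.9g} {n[1]:.9g} {n[2]:.9g}\n"
                    "  outer loop\n")
            for v in p:
                f.write(f"    vertex {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
            f.write("  endloop\nendfacet\n")
        f.write("endsolid isosurface\n")
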