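"""Minimal text-based mesh/field writers (VTU and Gmsh MSH v2.2).

Only the small subset needed by this package is implemented: 2D quadrilateral
meshes with per-point and per-cell scalar/vector data, written as ASCII so the
artifacts stay text-only and diffable.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

__all__ = ["write_vtu", "write_msh", "read_msh", "write_json"]


def _fmt(a: np.ndarray) -> str:
    return " ".join(f"{v:.9g}" for v in np.asarray(a).ravel())


def write_vtu(path, mesh, point_data=None, cell_data=None) -> None:
    """Write a quad mesh (+ optional nodal/element fields) as ASCII .vtu."""
    nodes = np.asarray(mesh.nodes, dtype=float)
    elems = np.asarray(mesh.elements, dtype=int)
    npts, ncel = len(nodes), len(elems)
    xyz = np.column_stack([nodes, np.zeros(npts)])

    lines = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
        "<UnstructuredGrid>",
        f'<Piece NumberOfPoints="{npts}" NumberOfCells="{ncel}">',
        "<Points>",
        '<DataArray type="Float64" NumberOfComponents="3" format="ascii">',
        _fmt(xyz),
        "</DataArray>",
        "</Points>",
        "<Cells>",
        '<DataArray type="Int64" Name="connectivity" format="ascii">',
        _fmt(elems),
        "</DataArray>",
        '<DataArray type="Int64" Name="offsets" format="ascii">',
        _fmt(4 * np.arange(1, ncel + 1)),
        "</DataArray>",
        '<DataArray type="UInt8" Name="types" format="ascii">',
        _fmt(np.full(ncel, 9)),  # VTK_QUAD
        "</DataArray>",
        "</Cells>",
    ]

    def data_block(name, arrays):
        out = [f"<{name}>"]
        for key, arr in (arrays or {}).items():
            arr = np.asarray(arr, dtype=float)
            ncomp = 1 if arr.ndim == 1 else arr.shape[1]
            if ncomp == 2:  # pad vectors to 3D for VTK
                arr = np.column_stack([arr, np.zeros(len(arr))])
                ncomp = 3
            out.append(
                f'<DataArray type="Float64" Name="{key}" '
                f'NumberOfComponents="{ncomp}" format="ascii">'
            )
            out.append(_fmt(arr))
            out.append("</DataArray>")
        out.append(f"</{name}>")
        return out

    lines += data_block("PointData", point_data)
    cdata = dict(cell_data or {})
    cdata.setdefault("region", mesh.region)
    lines += data_block("CellData", cdata)
    lines += ["</Piece>", "</UnstructuredGrid>", "</VTKFile>"]
    Path(path).write_text("\n".join(lines))


def write_msh(path, mesh) -> None:
    """Write the mesh in Gmsh MSH 2.2 ASCII (quads, physical tag = region)."""
    nodes = np.asarray(mesh.nodes, dtype=float)
    elems = np.asarray(mesh.elements, dtype=int)
    lines = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat", "$Nodes", str(len(nodes))]
    for i, (x, y) in enumerate(nodes, start=1):
        lines.append(f"{i} {x:.12g} {y:.12g} 0")
    lines += ["$EndNodes", "$Elements", str(len(elems))]
    for e, quad in enumerate(elems, start=1):
        reg = int(mesh.region[e - 1])
        n = " ".join(str(v + 1) for v in quad)
        lines.append(f"{e} 3 2 {reg} {reg} {n}")  # type 3 = 4-node quad
    lines += ["$EndElements"]
    Path(path).write_text("\n".join(lines))


def read_msh(path):
    """Read a MSH 2.2 quad mesh written by :func:`write_msh`.

    Returns ``(nodes, elements, region)``.
    """
    text = Path(path).read_text().splitlines()
    it = iter(text)
    nodes, elems, region = [], [], []
    for line in it:
        if line.strip() == "$Nodes":
            n = int(next(it))
            for _ in range(n):
                parts = next(it).split()
                nodes.append([float(parts[1]), float(parts[2])])
        elif line.strip() == "$Elements":
            n = int(next(it))
            for _ in range(n):
                parts = next(it).split()
                ntags = int(parts[2])
                region.append(int(parts[3]))
                elems.append([int(v) - 1 for v in parts[3 + ntags :]])
    return (
        np.asarray(nodes, dtype=float),
        np.asarray(elems, dtype=int),
        np.asarray(region, dtype=int),
    )


def write_json(path, obj) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))

    Path(path).write_text(json.dumps(obj, indent=2, default=default))
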