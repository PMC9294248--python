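"""Minimal ASCII VTK XML readers/writers (PolyData .vtp, ImageData .vti).

Covers exactly what the toolkit exchanges with flow solvers and viewers:
triangle surfaces with per-point arrays, and uniform voxel fields with
per-cell arrays. ASCII only; appended/binary encodings are out of scope.
"""

from __future__ import annotations

from pathlib import Path
from xml.etree import ElementTree as ET

import numpy as np


def _fmt_array(name: str, data: np.ndarray, indent: str) -> str:
    data = np.asarray(data)
    ncomp = 1 if data.ndim == 1 else data.shape[1]
    if np.issubdtype(data.dtype, np.integer):
        dtype, fmt = "Int64", "%d"
    else:
        dtype, fmt = "Float64", "%.17g"
    body = "\n".join(
        indent + " ".join(fmt % v for v in row)
        for row in np.atleast_2d(data.reshape(-1, ncomp))
    )
    head = (f'{indent}<DataArray type="{dtype}" Name="{name}" '
            f'NumberOfComponents="{ncomp}" format="ascii">')
    return f"{head}\n{body}\n{indent}</DataArray>"


def _parse_array(elem) -> np.ndarray:
    ncomp = int(elem.get("NumberOfComponents", "1"))
    vals = np.fromstring(elem.text.replace("\n", " "), sep=" ")
    if elem.get("type", "").startswith("Int"):
        vals = vals.astype(np.int64)
    return vals if ncomp == 1 else vals.reshape(-1, ncomp)


def write_polydata(path, vertices, faces, point_data=None) -> None:
    vertices = np.asarray(vertices, float).reshape(-1, 3)
    faces = np.asarray(faces, np.int64).reshape(-1, 3)
    point_data = point_data or {}
    ind = "      "
    parts = [
        '<?xml version="1.0"?>',
        '<VTKFile type="PolyData" version="1.0" byte_order="LittleEndian">',
        "  <PolyData>",
        f'    <Piece NumberOfPoints="{len(vertices)}" NumberOfPolys="{len(faces)}">',
        "    <Points>",
        _fmt_array("Points", vertices, ind),
        "    </Points>",
    ]
    if point_data:
        parts.append("    <PointData>")
        for name, arr in point_data.items():
            parts.append(_fmt_array(name, np.asarray(arr), ind))
        parts.append("    </PointData>")
    offsets = 3 * (np.arange(len(faces)) + 1)
    parts += [
        "    <Polys>",
        _fmt_array("connectivity", faces.ravel(), ind),
        _fmt_array("offsets", offsets, ind),
        "    </Polys>",
        "    </Piece>",
        "  </PolyData>",
        "</VTKFile>",
    ]
    Path(path).write_text("\n".join(parts))


def read_polydata(path):
    """Returns ``(vertices, faces, point_data)``; only triangle polys supported."""
    root = ET.parse(str(path)).getroot()
    piece = root.find("./PolyData/Piece")
    if piece is None:
        raise IOError(f"{path}: not a VTK XML PolyData file")
    pts = _parse_array(piece.find("./Points/DataArray")).reshape(-1, 3)
    conn = offs = None
    for arr in piece.findall("./Polys/DataArray"):
        if arr.get("Name") == "connectivity":
            conn = _parse_array(arr).astype(np.int64).ravel()
        elif arr.get("Name") == "offsets":
            offs = _parse_array(arr).astype(np.int64).ravel()
    if conn is None or offs is None:
        raise IOError(f"{path}: missing connectivity/offsets")
    sizes = np.diff(np.concatenate([[0], offs]))
    if np.any(sizes != 3):
        raise IOError(f"{path}: non-triangle polys present")
    faces = conn.reshape(-1, 3)
    point_data = {}
    pd = piece.find("./PointData")
    if pd is not None:
        for arr in pd.findall("DataArray"):
            point_data[arr.get("Name")] = _parse_array(arr)
    return pts, faces, point_data


def write_imagedata(path, dims, spacing, origin, cell_data) -> None:
    """Uniform grid with per-cell arrays; ``dims`` is the cell count (nx,ny,nz)."""
    nx, ny, nz = dims
    ext = f"0 {nx} 0 {ny} 0 {nz}"
    ind = "      "
    parts = [
        '<?xml version="1.0"?>',
        '<VTKFile type="ImageData" version="1.0" byte_order="LittleEndian">',
        f'  <ImageData WholeExtent="{ext}" Origin="{origin[0]} {origin[1]} {origin[2]}" '
        f'Spacing="{spacing[0]} {spacing[1]} {spacing[2]}">',
        f'    <Piece Extent="{ext}">',
        "    <CellData>",
    ]
    for name, arr in cell_data.items():
        arr = np.asarray(arr)
        ncomp = 1 if arr.ndim == 3 else arr.shape[3]
        flat = arr.reshape(nx, ny, nz, ncomp).transpose(2, 1, 0, 3).reshape(-1, ncomp)
        parts.append(_fmt_array(name, flat if ncomp > 1 else flat.ravel(), ind))
    parts += ["    </CellData>", "    </Piece>", "  </ImageData>", "</VTKFile>"]
    Path(path).write_text("\n".join(parts))


def read_imagedata(path):
    """Returns ``(dims, spacing, origin, cell_data)`` with x-fastest arrays
    reshaped to (nx, ny, nz[, ncomp])."""
    root = ET.parse(str(path)).getroot()
    img = root.find("./ImageData")
    if img is None:
        raise IOError(f"{path}: not a VTK XML ImageData file")
    ext = [int(v) for v in img.get("WholeExtent").split()]
    dims = (ext[1] - ext[0], ext[3] - ext[2], ext[5] - ext[4])
    spacing = tuple(float(v) for v in img.get("Spacing").split())
    origin = tuple(float(v) for v in img.get("Origin").split())
    cell_data = {}
    nx, ny, nz = dims
    for arr in img.findall("./Piece/CellData/DataArray"):
        vals = _parse_array(arr)
        ncomp = 1 if vals.ndim == 1 else vals.shape[1]
        vals = vals.reshape(nz, ny, nx, ncomp).transpose(2, 1, 0, 3)
        cell_data[arr.get("Name")] = vals[..., 0] if ncomp == 1 else vals
    return dims, spacing, origin, cell_data
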