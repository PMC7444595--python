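"""File formats: XML PolyData (.vtp) meshes and MRC volumes.

Both formats are written/read directly:

* ``.vtp`` — the ASCII flavor of the VTK XML PolyData format, with named
  per-triangle (CellData) arrays.  Float payloads are formatted with 17
  significant digits, so float64 arrays round-trip bit-identically.
* ``.mrc`` — the MRC2014 volume layout (1024-byte header + raster), enough
  for binary segmentations: modes 0 (int8), 1 (int16), 2 (float32) and 6
  (uint16), cubic voxel size from the cell dimensions.
"""

from __future__ import annotations

import warnings
import xml.etree.ElementTree as ET

import numpy as np

from .mesh import TriangleMesh


class FormatError(ValueError):
    """Raised for malformed .vtp or .mrc input."""


# ----------------------------------------------------------------------
# VTP
# ----------------------------------------------------------------------
def _fmt_array(arr: np.ndarray) -> str:
    flat = np.asarray(arr).ravel()
    if np.issubdtype(flat.dtype, np.floating):
        return " ".join(format(x, ".17g") for x in flat)
    return " ".join(str(int(x)) for x in flat)


def write_vtp(mesh: TriangleMesh, path) -> None:
    """Write a mesh and its per-triangle attribute arrays as ASCII .vtp."""
    n_pts, n_polys = len(mesh.vertices), mesh.n_triangles
    lines = [
        '<?xml version="1.0"?>',
        '<VTKFile type="PolyData" version="0.1" byte_order="LittleEndian">',
        "  <PolyData>",
        f'    <Piece NumberOfPoints="{n_pts}" NumberOfVerts="0" '
        f'NumberOfLines="0" NumberOfStrips="0" NumberOfPolys="{n_polys}">',
        "      <Points>",
        '        <DataArray type="Float64" NumberOfComponents="3" '
        'format="ascii">',
        "          " + _fmt_array(mesh.vertices),
        "        </DataArray>",
        "      </Points>",
        "      <Polys>",
        '        <DataArray type="Int64" Name="connectivity" format="ascii">',
        "          " + _fmt_array(mesh.faces),
        "        </DataArray>",
        '        <DataArray type="Int64" Name="offsets" format="ascii">',
        "          " + _fmt_array(3 * np.arange(1, n_polys + 1)),
        "        </DataArray>",
        "      </Polys>",
        "      <CellData>",
    ]
    for name, arr in mesh.attributes.items():
        arr = np.asarray(arr)
        ncomp = 1 if arr.ndim == 1 else arr.shape[1]
        if len(arr) != n_polys:
            raise ValueError(f"attribute {name!r} length mismatch")
        dtype = "Float64" if np.issubdtype(arr.dtype, np.floating) else "Int64"
        lines += [
            f'        <DataArray type="{dtype}" Name="{name}" '
            f'NumberOfComponents="{ncomp}" format="ascii">',
            "          " + _fmt_array(arr.astype(np.float64 if dtype == "Float64" else np.int64)),
            "        </DataArray>",
        ]
    lines += [
        "      </CellData>",
        "    </Piece>",
        "  </PolyData>",
        "</VTKFile>",
        "",
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(lines))


def _parse_array(elem: ET.Element) -> np.ndarray:
    tokens = (elem.text or "").split()
    dtype = np.float64 if elem.get("type", "Float64").startswith("Float") else np.int64
    return np.array(tokens, dtype=dtype)


def read_vtp(path) -> TriangleMesh:
    """Read an ASCII .vtp file written by :func:`write_vtp` (or compatible)."""
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise FormatError(f"malformed .vtp file {path}: {exc}") from exc
    root = tree.getroot()
    piece = root.find(".//Piece")
    if piece is None:
        raise FormatError(f"{path}: no <Piece> element (not a PolyData file?)")
    pts_el = piece.find("./Points/DataArray")
    if pts_el is None:
        raise FormatError(f"{path}: missing Points array")
    vertices = _parse_array(pts_el).reshape(-1, 3)
    conn = off = None
    for da in piece.findall("./Polys/DataArray"):
        if da.get("Name") == "connectivity":
            conn = _parse_array(da).astype(np.int64)
        elif da.get("Name") == "offsets":
            off = _parse_array(da).astype(np.int64)
    if conn is None or off is None:
        raise FormatError(f"{path}: missing Polys connectivity/offsets")
    if len(off) and not np.all(np.diff(np.concatenate([[0], off])) == 3):
        raise FormatError(f"{path}: non-triangular polys are not supported")
    mesh = TriangleMesh(vertices, conn.reshape(-1, 3))
    for da in piece.findall("./CellData/DataArray"):
        name = da.get("Name", "unnamed")
        arr = _parse_array(da)
        ncomp = int(da.get("NumberOfComponents", "1"))
        if ncomp > 1:
            arr = arr.reshape(-1, ncomp)
        mesh.attributes[name] = arr
    return mesh


# ----------------------------------------------------------------------
# MRC
# ----------------------------------------------------------------------
_MRC_MODES = {0: np.int8, 1: np.int16, 2: np.float32, 6: np.uint16}


def write_mrc(data: np.ndarray, path, voxel_size: float = 1.0) -> None:
    """Write a 3D volume as MRC2014 (mode 2 float32, or mode 0 for int8)."""
    data = np.asarray(data)
    if data.ndim != 3:
        raise ValueError("volume must be 3D")
    if data.dtype == np.int8:
        mode, payload = 0, data
    else:
        mode, payload = 2, data.astype(np.float32)
    nz, ny, nx = data.shape
    header = np.zeros(256, dtype=np.int32)
    fheader = header.view(np.float32)
    header[0:3] = (nx, ny, nz)
    header[3] = mode
    header[7:10] = (nx, ny, nz)  # mx, my, mz
    fheader[10:13] = (nx * voxel_size, ny * voxel_size, nz * voxel_size)
    fheader[13:16] = (90.0, 90.0, 90.0)
    header[16:19] = (1, 2, 3)  # mapc, mapr, maps
    fheader[19] = float(payload.min()) if payload.size else 0.0
    fheader[20] = float(payload.max()) if payload.size else 0.0
    fheader[21] = float(payload.mean()) if payload.size else 0.0
    header[22] = 1  # ispg
    header[52] = int.from_bytes(b"MAP ", "little")
    header[53] = int.from_bytes(bytes([0x44, 0x44, 0, 0]), "little")  # machst
    with open(path, "wb") as fh:
        fh.write(header.tobytes())
        fh.write(np.ascontiguousarray(payload).tobytes())


def read_mrc(path, binarize: bool = False) -> tuple[np.ndarray, float]:
    """Read an MRC volume; returns ``(data[z, y, x], voxel_size)``.

    With ``binarize=True``, non-binary volumes are coerced to {0, 1} via a
    ``> 0`` threshold (with a warning).  Anisotropic voxel sizes are rejected.
    """
    with open(path, "rb") as fh:
        raw = fh.read(1024)
        if len(raw) < 1024:
            raise FormatError(f"{path}: truncated MRC header")
        header = np.frombuffer(raw, dtype=np.int32).copy()
        fheader = header.view(np.float32)
        nx, ny, nz = (int(x) for x in header[0:3])
        mode = int(header[3])
        if mode not in _MRC_MODES:
            raise FormatError(f"{path}: unsupported MRC mode {mode}")
        if min(nx, ny, nz) <= 0:
            raise FormatError(f"{path}: invalid MRC dimensions {(nx, ny, nz)}")
        mx, my, mz = (int(x) for x in header[7:10])
        sizes = []
        for cell, m, n in zip(fheader[10:13], (mx, my, mz), (nx, ny, nz)):
            denom = m if m > 0 else n
            sizes.append(float(cell) / denom if cell > 0 else 1.0)
        if not np.allclose(sizes, sizes[0], rtol=1e-4):
            raise FormatError(
                f"{path}: anisotropic voxel size {tuple(sizes)} is unsupported"
            )
        nsymbt = int(header[23])
        fh.seek(1024 + nsymbt)
        dtype = _MRC_MODES[mode]
        count = nx * ny * nz
        data = np.frombuffer(fh.read(count * dtype().itemsize), dtype=dtype)
        if data.size != count:
            raise FormatError(f"{path}: truncated MRC data section")
        data = data.reshape(nz, ny, nx).copy()
    if binarize:
        uniq = np.unique(data)
        if not np.isin(uniq, (0, 1)).all():
            warnings.warn(
                f"{path}: volume is not binary; coercing via > 0 threshold",
                stacklevel=2,
            )
        data = (data > 0).astype(np.uint8)
    return data, sizes[0]
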