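"""Plain-text I/O: legacy ASCII VTK, ASCII PLY, CSV/XYZ point clouds, CSV tables.

Meshes travel with attached per-node and per-element fields. The boundary node
sets (rim / hole) are serialized as an integer per-node field ``boundary_flag``
(0 interior, 1 rim, 2 hole) so a round trip is lossless.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError
from .mesh import PointCloud3D, TriSurfaceMesh

__all__ = [
    "write_mesh_bundle",
    "read_mesh_bundle",
    "write_point_cloud",
    "read_point_cloud",
    "write_displacement_csv",
    "read_displacement_csv",
    "write_parameter_table",
    "read_parameter_table",
]

BOUNDARY_FIELD = "boundary_flag"


def _boundary_field(mesh: TriSurfaceMesh) -> np.ndarray:
    flag = np.zeros(mesh.n_nodes, dtype=float)
    flag[mesh.rim_nodes] = 1
    flag[mesh.hole_nodes] = 2
    return flag


def _mesh_from_arrays(nodes, tris, node_data) -> TriSurfaceMesh:
    flag = node_data.get(BOUNDARY_FIELD)
    rim = np.where(np.rint(flag) == 1)[0] if flag is not None else np.empty(0, int)
    hole = np.where(np.rint(flag) == 2)[0] if flag is not None else np.empty(0, int)
    return TriSurfaceMesh(nodes, tris, rim_nodes=rim, hole_nodes=hole)


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

def write_mesh_bundle(path, mesh: TriSurfaceMesh, node_data=None, cell_data=None):
    """Write mesh + fields to ``.vtk`` (legacy ASCII) or ``.ply`` (ASCII)."""
    path = Path(path)
    node_data = dict(node_data or {})
    cell_data = dict(cell_data or {})
    node_data.setdefault(BOUNDARY_FIELD, _boundary_field(mesh))
    if path.suffix.lower() == ".vtk":
        _write_vtk(path, mesh, node_data, cell_data)
    elif path.suffix.lower() == ".ply":
        _write_ply(path, mesh, node_data, cell_data)
    else:
        raise ParseError(f"unknown mesh extension {path.suffix!r} (use .vtk or .ply)")


def read_mesh_bundle(path):
    """Read a mesh bundle; returns (mesh, node_data, cell_data)."""
    path = Path(path)
    if path.suffix.lower() == ".vtk":
        nodes, tris, nd, cd = _read_vtk(path)
    elif path.suffix.lower() == ".ply":
        nodes, tris, nd, cd = _read_ply(path)
    else:
        raise ParseError(f"unknown mesh extension {path.suffix!r} (use .vtk or .ply)")
    mesh = _mesh_from_arrays(nodes, tris, nd)
    nd.pop(BOUNDARY_FIELD, None)
    return mesh, nd, cd


# ---------------------------------------------------------------------------
# legacy VTK
# ---------------------------------------------------------------------------

def _fmt(a):
    return " ".join(repr(float(v)) for v in np.atleast_1d(a))


def _write_vtk(path, mesh, node_data, cell_data):
    lines = [
        "# vtk DataFile Version 3.0",
        "scleramap surface bundle",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_nodes} double",
    ]
    lines += [_fmt(p) for p in mesh.nodes]
    m = mesh.n_triangles
    lines.append(f"CELLS {m} {4 * m}")
    lines += [f"3 {a} {b} {c}" for a, b, c in mesh.triangles]
    lines.append(f"CELL_TYPES {m}")
    lines += ["5"] * m

    def emit(block_name, count, data):
        out = [f"{block_name} {count}"]
        for name, arr in data.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim == 1:
                out.append(f"SCALARS {name} double 1")
                out.append("LOOKUP_TABLE default")
                out += [repr(float(v)) for v in arr]
            elif arr.ndim == 2 and arr.shape[1] == 3:
                out.append(f"VECTORS {name} double")
                out += [_fmt(v) for v in arr]
            else:
                raise ParseError(f"field {name!r}: unsupported shape {arr.shape}")
        return out

    if node_data:
        lines += emit("POINT_DATA", mesh.n_nodes, node_data)
    if cell_data:
        lines += emit("CELL_DATA", m, cell_data)
    Path(path).write_text("\n".join(lines) + "\n")


def _read_vtk(path):
    tokens_iter = _TokenStream(Path(path))
    t = tokens_iter
    try:
        t.expect_line_startswith("# vtk")
        t.next_line()  # title
        if t.next_line().strip().upper() != "ASCII":
            raise ParseError(f"{path}: only ASCII legacy VTK supported")
        if "UNSTRUCTURED_GRID" not in t.next_line().upper():
            raise ParseError(f"{path}: expected DATASET UNSTRUCTURED_GRID")
        hdr = t.next_line().split()
        n = int(hdr[1])
        nodes = np.array(t.take_floats(3 * n)).reshape(n, 3)
        hdr = t.next_nonempty().split()
        if hdr[0].upper() != "CELLS":
            raise ParseError(f"{path}: expected CELLS, got {hdr[0]!r}")
        m = int(hdr[1])
        raw = t.take_floats(int(hdr[2]))
        tris = []
        i = 0
        for _ in range(m):
            k = int(raw[i])
            if k != 3:
                raise ParseError(f"{path}: cell with {k} nodes; only triangles supported")
            tris.append([int(raw[i + 1]), int(raw[i + 2]), int(raw[i + 3])])
            i += k + 1
        hdr = t.next_nonempty().split()
        if hdr[0].upper() != "CELL_TYPES":
            raise ParseError(f"{path}: expected CELL_TYPES")
        t.take_floats(m)
        node_data, cell_data = {}, {}
        current, count = None, 0
        while True:
            line = t.next_nonempty(optional=True)
            if line is None:
                break
            w = line.split()
            key = w[0].upper()
            if key == "POINT_DATA":
                current, count = node_data, int(w[1])
            elif key == "CELL_DATA":
                current, count = cell_data, int(w[1])
            elif key == "SCALARS":
                t.next_line()  # LOOKUP_TABLE
                current[w[1]] = np.array(t.take_floats(count))
            elif key == "VECTORS":
                current[w[1]] = np.array(t.take_floats(3 * count)).reshape(count, 3)
            else:
                raise ParseError(f"{path}: unexpected record {w[0]!r}")
        return nodes, np.array(tris, int), node_data, cell_data
    except (ValueError, IndexError, StopIteration) as exc:
        raise ParseError(f"{path}: malformed VTK near line {t.lineno}: {exc}") from exc


class _TokenStream:
    def __init__(self, path: Path):
        self._lines = path.read_text().splitlines()
        self.lineno = 0
        self._buf: list[str] = []

    def next_line(self) -> str:
        if self.lineno >= len(self._lines):
            raise StopIteration("unexpected end of file")
        line = self._lines[self.lineno]
        self.lineno += 1
        return line

    def next_nonempty(self, optional=False):
        while self.lineno < len(self._lines):
            line = self.next_line()
            if line.strip():
                return line
        if optional:
            return None
        raise StopIteration("unexpected end of file")

    def expect_line_startswith(self, prefix):
        if not self.next_line().startswith(prefix):
            raise ParseError(f"expected line starting with {prefix!r}")

    def take_floats(self, n):
        vals: list[float] = []
        while len(vals) < n:
            vals.extend(float(x) for x in self.next_nonempty().split())
        if len(vals) != n:
            raise ParseError(f"expected {n} numeric values, got {len(vals)}")
        return vals


# ---------------------------------------------------------------------------
# ASCII PLY
# ---------------------------------------------------------------------------

def _write_ply(path, mesh, node_data, cell_data):
    nscal = {k: np.asarray(v, float) for k, v in node_data.items() if np.asarray(v).ndim == 1}
    cscal = {k: np.asarray(v, float) for k, v in cell_data.items() if np.asarray(v).ndim == 1}
    if len(nscal) != len(node_data) or len(cscal) != len(cell_data):
        raise ParseError("PLY bundles support scalar fields only; use .vtk for vectors")
    buf = _io.StringIO()
    buf.write("ply\nformat ascii 1.0\ncomment scleramap surface bundle\n")
    buf.write(f"element vertex {mesh.n_nodes}\n")
    for ax in "xyz":
        buf.write(f"property double {ax}\n")
    for name in nscal:
        buf.write(f"property double {name}\n")
    buf.write(f"element face {mesh.n_triangles}\n")
    buf.write("property list uchar int vertex_indices\n")
    for name in cscal:
        buf.write(f"property double {name}\n")
    buf.write("end_header\n")
    cols = [mesh.nodes] + [v[:, None] for v in nscal.values()]
    for row in np.hstack(cols):
        buf.write(_fmt(row) + "\n")
    cvals = list(cscal.values())
    for i, (a, b, c) in enumerate(mesh.triangles):
        extra = "".join(f" {repr(float(v[i]))}" for v in cvals)
        buf.write(f"3 {a} {b} {c}{extra}\n")
    Path(path).write_text(buf.getvalue())


def _read_ply(path):
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].strip() != "ply":
        raise ParseError(f"{path}: not a PLY file")
    i = 1
    elements = []  # (name, count, [prop names]) in order
    while i < len(lines):
        w = lines[i].split()
        i += 1
        if not w:
            continue
        if w[0] == "format" and w[1] != "ascii":
            raise ParseError(f"{path}: only ascii PLY supported")
        elif w[0] == "element":
            elements.append((w[1], int(w[2]), []))
        elif w[0] == "property":
            if w[1] == "list":
                elements[-1][2].append(("list", w[-1]))
            else:
                elements[-1][2].append(("scalar", w[-1]))
        elif w[0] == "end_header":
            break
    body = [ln for ln in lines[i:] if ln.strip()]
    nodes = tris = None
    node_data, cell_data = {}, {}
    row = 0
    try:
        for name, count, props in elements:
            chunk = body[row : row + count]
            row += count
            if name == "vertex":
                vals = np.array([[float(x) for x in ln.split()] for ln in chunk])
                if vals.shape[1] != len(props):
                    raise ParseError(f"{path}: vertex row width mismatch")
                nodes = vals[:, :3]
                for j, (_, pname) in enumerate(props[3:], start=3):
                    node_data[pname] = vals[:, j]
            elif name == "face":
                tris = []
                extras = {pname: [] for kind, pname in props if kind == "scalar"}
                for ln in chunk:
                    w = ln.split()
                    k = int(w[0])
                    if k != 3:
                        raise ParseError(f"{path}: face with {k} vertices; triangles only")
                    tris.append([int(w[1]), int(w[2]), int(w[3])])
                    for j, (kind, pname) in enumerate(p for p in props if p[0] == "scalar"):
                        extras[pname].append(float(w[4 + j]))
                tris = np.array(tris, int)
                for pname, v in extras.items():
                    cell_data[pname] = np.array(v)
    except (ValueError, IndexError) as exc:
        raise ParseError(f"{path}: malformed PLY body at record {row}: {exc}") from exc
    if nodes is None or tris is None:
        raise ParseError(f"{path}: PLY missing vertex or face element")
    return nodes, tris, node_data, cell_data


# ---------------------------------------------------------------------------
# point clouds and tables
# ---------------------------------------------------------------------------

def write_point_cloud(path, cloud: PointCloud3D):
    """One point per row: ``x,y,z`` (CSV with header) or whitespace ``.xyz``."""
    path = Path(path)
    if path.suffix.lower() == ".xyz":
        np.savetxt(path, cloud.points, fmt="%.12g")
    else:
        pd.DataFrame(cloud.points, columns=["x", "y", "z"]).to_csv(path, index=False)


def read_point_cloud(path) -> PointCloud3D:
    path = Path(path)
    try:
        if path.suffix.lower() == ".xyz":
            pts = np.loadtxt(path, ndmin=2)
        else:
            pts = pd.read_csv(path)[["x", "y", "z"]].to_numpy(float)
    except Exception as exc:
        raise ParseError(f"{path}: cannot parse point cloud: {exc}") from exc
    return PointCloud3D(pts)


def write_displacement_csv(path, pressures_mmhg, u):
    """Long-format displacement table: node_id, pressure_mmHg, ux/uy/uz in mm."""
    u = np.asarray(u, float)
    nstep, nnode, _ = u.shape
    frames = []
    for s, p in enumerate(pressures_mmhg):
        frames.append(
            pd.DataFrame(
                {
                    "node_id": np.arange(nnode),
                    "pressure_mmHg": float(p),
                    "ux_mm": u[s, :, 0],
                    "uy_mm": u[s, :, 1],
                    "uz_mm": u[s, :, 2],
                }
            )
        )
    pd.concat(frames).to_csv(path, index=False)


def read_displacement_csv(path):
    """Returns (pressures_mmHg sorted ascending, u of shape (nstep, nnode, 3))."""
    try:
        df = pd.read_csv(path)
        pressures = np.sort(df["pressure_mmHg"].unique())
        nnode = df["node_id"].max() + 1
        u = np.zeros((len(pressures), int(nnode), 3))
        for s, p in enumerate(pressures):
            sub = df[df["pressure_mmHg"] == p].sort_values("node_id")
            u[s, sub["node_id"].to_numpy(int)] = sub[["ux_mm", "uy_mm", "uz_mm"]].to_numpy(float)
    except KeyError as exc:
        raise ParseError(f"{path}: missing column {exc}") from exc
    except Exception as exc:
        raise ParseError(f"{path}: cannot parse displacement table: {exc}") from exc
    return pressures, u


def write_parameter_table(path, rows):
    """Rows: dicts with subdomain_id, C10_kPa, k1_kPa, k2, kappa, ... columns."""
    pd.DataFrame(rows).to_csv(path, index=False)


def read_parameter_table(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"{path}: cannot parse parameter table: {exc}") from exc
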