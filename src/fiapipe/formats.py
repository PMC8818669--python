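"""Readers/writers for surface meshes (STL, OBJ) and centerlines (CSV).

STL stores loose triangles, so vertices are welded on load by exact
coordinate match after rounding to ``weld_decimals``.
"""

from __future__ import annotations

import os
import struct

import numpy as np
import pandas as pd

from .geometry import Centerline, SurfaceMesh

__all__ = [
    "read_mesh",
    "write_mesh",
    "read_stl",
    "write_stl",
    "read_obj",
    "write_obj",
    "read_centerline",
    "read_centerline_csv",
    "read_centerline_obj",
    "write_centerline_csv",
]

_WELD_DECIMALS = 6


def _weld(tri_verts: np.ndarray) -> SurfaceMesh:
    """Build an indexed mesh from an (n_tri, 3, 3) soup of triangle corners."""
    flat = tri_verts.reshape(-1, 3)
    key = np.round(flat, _WELD_DECIMALS)
    uniq, inverse = np.unique(key, axis=0, return_inverse=True)
    # keep the un-rounded coordinate of the first occurrence of each vertex
    first = np.full(len(uniq), -1, dtype=np.int64)
    seen = np.zeros(len(uniq), dtype=bool)
    for i, j in enumerate(inverse):
        if not seen[j]:
            first[j] = i
            seen[j] = True
    verts = flat[first]
    tris = inverse.reshape(-1, 3)
    keep = (tris[:, 0] != tris[:, 1]) & (tris[:, 1] != tris[:, 2]) & (tris[:, 0] != tris[:, 2])
    return SurfaceMesh(verts, tris[keep])


def read_stl(path: str) -> SurfaceMesh:
    with open(path, "rb") as fh:
        head = fh.read(5)
    if head == b"solid":
        try:
            return _read_stl_ascii(path)
        except ValueError:
            pass  # binary file whose header happens to start with "solid"
    return _read_stl_binary(path)


def _read_stl_ascii(path: str) -> SurfaceMesh:
    pts = []
    with open(path, "r", errors="replace") as fh:
        for line in fh:
            tok = line.split()
            if tok and tok[0] == "vertex":
                pts.append([float(tok[1]), float(tok[2]), float(tok[3])])
    if not pts or len(pts) % 3:
        raise ValueError(f"not a valid ASCII STL: {path}")
    return _weld(np.array(pts).reshape(-1, 3, 3))


def _read_stl_binary(path: str) -> SurfaceMesh:
    with open(path, "rb") as fh:
        fh.seek(80)
        (n_tri,) = struct.unpack("<I", fh.read(4))
        data = np.frombuffer(fh.read(n_tri * 50), dtype=np.uint8)
    if data.size != n_tri * 50:
        raise ValueError(f"truncated binary STL: {path}")
    rec = data.reshape(n_tri, 50)
    floats = rec[:, :48].copy().view("<f4").reshape(n_tri, 12)
    return _weld(floats[:, 3:12].astype(float).reshape(n_tri, 3, 3))


def write_stl(mesh: SurfaceMesh, path: str, binary: bool = False) -> None:
    v = mesh.vertices[mesh.triangles]  # (nt, 3, 3)
    n = mesh.triangle_normals()
    if binary:
        with open(path, "wb") as fh:
            fh.write(b"\0" * 80)
            fh.write(struct.pack("<I", len(v)))
            rec = np.zeros((len(v), 50), dtype=np.uint8)
            floats = np.concatenate([n[:, None, :], v], axis=1).astype("<f4")
            rec[:, :48] = floats.reshape(len(v), 12).view(np.uint8).reshape(len(v), 48)
            fh.write(rec.tobytes())
    else:
        with open(path, "w") as fh:
            fh.write("solid mesh\n")
            for (nx, ny, nz), tri in zip(n, v):
                fh.write(f"facet normal {nx:.9g} {ny:.9g} {nz:.9g}\n outer loop\n")
                for x, y, z in tri:
                    fh.write(f"  vertex {x:.9g} {y:.9g} {z:.9g}\n")
                fh.write(" endloop\nendfacet\n")
            fh.write("endsolid mesh\n")


def read_obj(path: str) -> SurfaceMesh:
    verts, tris = [], []
    with open(path) as fh:
        for line in fh:
            tok = line.split()
            if not tok:
                continue
            if tok[0] == "v":
                verts.append([float(tok[1]), float(tok[2]), float(tok[3])])
            elif tok[0] == "f":
                idx = [int(t.split("/")[0]) - 1 for t in tok[1:]]
                for k in range(1, len(idx) - 1):  # fan-triangulate polygons
                    tris.append([idx[0], idx[k], idx[k + 1]])
    if not verts:
        raise ValueError(f"no vertices in OBJ: {path}")
    return SurfaceMesh(np.array(verts), np.array(tris))


def write_obj(mesh: SurfaceMesh, path: str) -> None:
    with open(path, "w") as fh:
        for x, y, z in mesh.vertices:
            fh.write(f"v {x:.9g} {y:.9g} {z:.9g}\n")
        for a, b, c in mesh.triangles + 1:
            fh.write(f"f {a} {b} {c}\n")


def read_mesh(path: str) -> SurfaceMesh:
    ext = os.path.splitext(path)[1].lower()
    if ext == ".stl":
        return read_stl(path)
    if ext == ".obj":
        return read_obj(path)
    raise ValueError(f"unsupported mesh format: {ext}")


def write_mesh(mesh: SurfaceMesh, path: str, **kw) -> None:
    ext = os.path.splitext(path)[1].lower()
    if ext == ".stl":
        write_stl(mesh, path, **kw)
    elif ext == ".obj":
        write_obj(mesh, path)
    else:
        raise ValueError(f"unsupported mesh format: {ext}")


def read_centerline_obj(path: str) -> Centerline:
    """Read a centerline from an OBJ polyline (``v`` records plus ``l`` lines)."""
    verts, order = [], []
    with open(path) as fh:
        for line in fh:
            tok = line.split()
            if not tok:
                continue
            if tok[0] == "v":
                verts.append([float(tok[1]), float(tok[2]), float(tok[3])])
            elif tok[0] == "l":
                order.extend(int(t) - 1 for t in tok[1:])
    if not order:
        raise ValueError(f"no polyline records in {path}")
    return Centerline(np.array(verts)[order])


def read_centerline(path: str) -> Centerline:
    if os.path.splitext(path)[1].lower() == ".obj":
        return read_centerline_obj(path)
    return read_centerline_csv(path)


def read_centerline_csv(path: str) -> Centerline:
    """Read a centerline from CSV with columns x, y, z (header required)."""
    df = pd.read_csv(path)
    cols = [c.strip().lower() for c in df.columns]
    missing = {"x", "y", "z"} - set(cols)
    if missing:
        raise ValueError(f"centerline CSV missing columns: {sorted(missing)}")
    df.columns = cols
    return Centerline(df[["x", "y", "z"]].to_numpy(dtype=float))


def write_centerline_csv(cl: Centerline, path: str) -> None:
    pd.DataFrame(cl.points, columns=["x", "y", "z"]).to_csv(path, index=False)
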