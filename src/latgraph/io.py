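"""Mesh and sample-table input/output.

Surface geometry is exchanged in open indexed-triangle formats (OFF, PLY,
OBJ); local activation time (LAT) observations travel as plain CSV with
``x,y,z,lat`` columns (coordinates in millimetres, LAT in milliseconds);
per-vertex result signals are written as ``vertex_index,x,y,z,lat`` CSV.
All indices are 0-based, both in memory and on disk.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import trimesh

__all__ = [
    "TriMesh",
    "LATSamples",
    "read_mesh",
    "write_mesh",
    "read_lat_samples",
    "write_lat_samples",
    "read_vertex_signal",
    "write_vertex_signal",
]

_MESH_FORMATS = ("off", "ply", "obj")


@dataclass(frozen=True)
class TriMesh:
    """Triangulated surface: ``vertices`` (n, 3) in mm, ``faces`` (t, 3) int."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self):
        verts = np.ascontiguousarray(np.asarray(self.vertices, dtype=float))
        faces = np.ascontiguousarray(np.asarray(self.faces, dtype=np.int64))
        if verts.ndim != 2 or verts.shape[1] != 3:
            raise ValueError("vertices must be an (n, 3) array")
        if faces.ndim != 2 or faces.shape[1] != 3:
            raise ValueError("faces must be a (t, 3) array of vertex indices")
        if len(verts) < 3 or len(faces) < 1:
            raise ValueError("mesh needs at least 3 vertices and 1 face")
        if not np.isfinite(verts).all():
            raise ValueError("non-finite vertex coordinate")
        if faces.min() < 0 or faces.max() >= len(verts):
            bad = np.where((faces < 0) | (faces >= len(verts)))[0][0]
            raise ValueError(f"face {bad} has an out-of-range vertex index")
        same = (
            (faces[:, 0] == faces[:, 1])
            | (faces[:, 1] == faces[:, 2])
            | (faces[:, 0] == faces[:, 2])
        )
        if same.any():
            raise ValueError(f"face {np.where(same)[0][0]} repeats a vertex index")
        undirected = np.sort(faces, axis=1)
        if len(np.unique(undirected, axis=0)) != len(faces):
            raise ValueError("duplicated face (as an unordered vertex triple)")
        object.__setattr__(self, "vertices", verts)
        object.__setattr__(self, "faces", faces)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)


@dataclass(frozen=True)
class LATSamples:
    """Scattered LAT observations: ``coords`` (m, 3) mm, ``values`` (m,) ms."""

    coords: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        coords = np.ascontiguousarray(np.asarray(self.coords, dtype=float))
        values = np.ascontiguousarray(np.asarray(self.values, dtype=float))
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coords must be an (m, 3) array")
        if values.ndim != 1 or len(values) != len(coords):
            raise ValueError("values must be a 1-d array matching coords")
        if len(values) < 1:
            raise ValueError("need at least one observation")
        if not (np.isfinite(coords).all() and np.isfinite(values).all()):
            raise ValueError("non-finite coordinate or LAT value")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return len(self.values)


def _infer_format(path: str, fmt: str) -> str:
    fmt = fmt.lower()
    if fmt == "auto":
        fmt = os.path.splitext(path)[1].lstrip(".").lower()
    if fmt not in _MESH_FORMATS:
        raise ValueError(f"unsupported mesh format {fmt!r}; expected one of {_MESH_FORMATS}")
    return fmt


def _check_triangular_text(path: str, fmt: str) -> None:
    # trimesh silently fans polygon faces into triangles; the contract here is
    # to reject them, so scan the (text) face records for arity > 3 first.
    with open(path, "r", errors="replace") as fh:
        lines = [ln.split("#")[0].strip() for ln in fh]
    lines = [ln for ln in lines if ln]
    if fmt == "obj":
        for i, ln in enumerate(lines):
            if ln.startswith("f ") and len(ln.split()) - 1 != 3:
                raise ValueError(f"non-triangular face in {path!r} (line {i})")
    elif fmt == "off":
        if not lines or not lines[0].upper().startswith("OFF"):
            return
        header = lines[0][3:].split() or lines[1].split()
        start = 1 if lines[0][3:].split() else 2
        n_v = int(header[0])
        for j, ln in enumerate(lines[start + n_v :]):
            tok = ln.split()
            if tok and int(tok[0]) != 3:
                raise ValueError(f"non-triangular face in {path!r} (face {j})")
    elif fmt == "ply":
        head = lines[: lines.index("end_header") + 1] if "end_header" in lines else []
        if any(ln.startswith("format ascii") for ln in head):
            n_v = n_f = 0
            for ln in head:
                if ln.startswith("element vertex"):
                    n_v = int(ln.split()[2])
                if ln.startswith("element face"):
                    n_f = int(ln.split()[2])
            body = lines[len(head) :]
            for j, ln in enumerate(body[n_v : n_v + n_f]):
                tok = ln.split()
                if tok and int(tok[0]) != 3:
                    raise ValueError(f"non-triangular face in {path!r} (face {j})")


def read_mesh(path: str, fmt: str = "auto") -> TriMesh:
    """Read an indexed triangle mesh from an OFF, PLY or OBJ file.

    Non-triangular faces are rejected rather than triangulated.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    fmt = _infer_format(path, fmt)
    _check_triangular_text(path, fmt)
    try:
        loaded = trimesh.load(path, file_type=fmt, process=False, force="mesh")
    except Exception as exc:  # noqa: BLE001 - normalise loader errors
        raise ValueError(f"could not parse {path!r} as a {fmt.upper()} mesh: {exc}") from exc
    faces = np.asarray(loaded.faces)
    if faces.size == 0:
        raise ValueError(f"{path!r} contains no faces")
    if faces.shape[1] != 3:
        raise ValueError(f"non-triangular face in {path!r}")
    return TriMesh(np.asarray(loaded.vertices, dtype=float), faces)


def write_mesh(path: str, mesh: TriMesh, fmt: str = "auto") -> None:
    """Write a :class:`TriMesh` to OFF/PLY/OBJ (ASCII where the format allows)."""
    fmt = _infer_format(path, fmt)
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    kwargs = {"encoding": "ascii"} if fmt == "ply" else {}
    data = trimesh.exchange.export.export_mesh(tm, path, file_type=fmt, **kwargs)
    del data


def read_lat_samples(path: str) -> LATSamples:
    """Read observations from CSV with header columns ``x,y,z,lat``."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path!r} is empty") from exc
    for col in ("x", "y", "z", "lat"):
        if col not in df.columns:
            raise ValueError(f"{path!r} is missing required column {col!r}")
    if len(df) == 0:
        raise ValueError(f"{path!r} has a header but no observations")
    sub = df[["x", "y", "z", "lat"]].apply(pd.to_numeric, errors="coerce")
    if sub.isna().any().any():
        row = int(sub.isna().any(axis=1).idxmax())
        raise ValueError(f"non-numeric cell in {path!r} at data row {row}")
    return LATSamples(sub[["x", "y", "z"]].to_numpy(), sub["lat"].to_numpy())


def write_lat_samples(path: str, samples: LATSamples) -> None:
    pd.DataFrame(
        {
            "x": samples.coords[:, 0],
            "y": samples.coords[:, 1],
            "z": samples.coords[:, 2],
            "lat": samples.values,
        }
    ).to_csv(path, index=False)


def write_vertex_signal(path: str, mesh: TriMesh, values: np.ndarray) -> None:
    """Write a per-vertex ms signal as ``vertex_index,x,y,z,lat`` CSV."""
    values = np.asarray(values, dtype=float)
    if values.shape != (mesh.n_vertices,):
        raise ValueError(
            f"signal length {values.shape} does not match vertex count {mesh.n_vertices}"
        )
    pd.DataFrame(
        {
            "vertex_index": np.arange(mesh.n_vertices),
            "x": mesh.vertices[:, 0],
            "y": mesh.vertices[:, 1],
            "z": mesh.vertices[:, 2],
            "lat": values,
        }
    ).to_csv(path, index=False)


def read_vertex_signal(path: str) -> np.ndarray:
    """Read back a per-vertex signal written by :func:`write_vertex_signal`."""
    df = pd.read_csv(path)
    for col in ("vertex_index", "lat"):
        if col not in df.columns:
            raise ValueError(f"{path!r} is missing required column {col!r}")
    order = np.argsort(df["vertex_index"].to_numpy())
    return df["lat"].to_numpy(dtype=float)[order]
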