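"""Mesh and geometry file I/O.

Labeled surface meshes are written as ASCII PLY (patch label in a per-face
integer property ``patch``) or ASCII OFF (label as the face 'color' slot,
a common OFF extension).  Ellipsoids travel as JSON sidecar files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .ellipsoid import Ellipsoid
from .mesh import TriSurfaceMesh


def save_ply(mesh: TriSurfaceMesh, path: str | Path) -> None:
    path = Path(path)
    lines = [
        "ply",
        "format ascii 1.0",
        "comment embryoshape labeled surface mesh (patch: 0=AB_outer 1=P1_outer 2=contact)",
        f"element vertex {len(mesh.vertices)}",
        "property float x",
        "property float y",
        "property float z",
        f"element face {len(mesh.triangles)}",
        "property list uchar int vertex_indices",
        "property int patch",
        "end_header",
    ]
    for v in mesh.vertices:
        lines.append(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}")
    for tri, p in zip(mesh.triangles, mesh.patch):
        lines.append(f"3 {tri[0]} {tri[1]} {tri[2]} {int(p)}")
    path.write_text("\n".join(lines) + "\n")


def load_ply(path: str | Path) -> TriSurfaceMesh:
    text = Path(path).read_text().splitlines()
    it = iter(text)
    if next(it).strip() != "ply":
        raise ValueError("not a PLY file")
    n_vert = n_face = None
    for line in it:
        t = line.split()
        if t[:2] == ["element", "vertex"]:
            n_vert = int(t[2])
        elif t[:2] == ["element", "face"]:
            n_face = int(t[2])
        elif t[0] == "end_header":
            break
    if n_vert is None or n_face is None:
        raise ValueError("malformed PLY header")
    verts = np.array([[float(x) for x in next(it).split()] for _ in range(n_vert)])
    tris, labels = [], []
    for _ in range(n_face):
        t = next(it).split()
        if t[0] != "3":
            raise ValueError("only triangle faces are supported")
        tris.append([int(t[1]), int(t[2]), int(t[3])])
        labels.append(int(t[4]))
    return TriSurfaceMesh(verts, np.array(tris), np.array(labels))


def save_off(mesh: TriSurfaceMesh, path: str | Path) -> None:
    path = Path(path)
    lines = ["OFF", f"{len(mesh.vertices)} {len(mesh.triangles)} 0"]
    for v in mesh.vertices:
        lines.append(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}")
    for tri, p in zip(mesh.triangles, mesh.patch):
        lines.append(f"3 {tri[0]} {tri[1]} {tri[2]} {int(p)}")
    path.write_text("\n".join(lines) + "\n")


def load_off(path: str | Path) -> TriSurfaceMesh:
    raw = [
        ln for ln in Path(path).read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    if raw[0].strip() != "OFF":
        raise ValueError("not an OFF file")
    n_vert, n_face, _ = (int(x) for x in raw[1].split())
    verts = np.array([[float(x) for x in ln.split()] for ln in raw[2 : 2 + n_vert]])
    tris, labels = [], []
    for ln in raw[2 + n_vert : 2 + n_vert + n_face]:
        t = ln.split()
        tris.append([int(t[1]), int(t[2]), int(t[3])])
        labels.append(int(t[4]) if len(t) > 4 else 0)
    return TriSurfaceMesh(verts, np.array(tris), np.array(labels))


def save_mesh(mesh: TriSurfaceMesh, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".ply":
        save_ply(mesh, path)
    elif path.suffix.lower() == ".off":
        save_off(mesh, path)
    else:
        raise ValueError(f"unsupported mesh format: {path.suffix}")


def load_mesh(path: str | Path) -> TriSurfaceMesh:
    path = Path(path)
    if path.suffix.lower() == ".ply":
        return load_ply(path)
    if path.suffix.lower() == ".off":
        return load_off(path)
    raise ValueError(f"unsupported mesh format: {path.suffix}")


def save_ellipsoid(e: Ellipsoid, path: str | Path) -> None:
    Path(path).write_text(json.dumps(e.to_dict(), indent=2, sort_keys=True) + "\n")


def load_ellipsoid(path: str | Path) -> Ellipsoid:
    return Ellipsoid.from_dict(json.loads(Path(path).read_text()))
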