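"""Mesh file I/O (ASCII OFF and Wavefront OBJ), backed by trimesh.

Vertices are interpreted as millimeters. GLB/GLTF is recognized as the
production atlas format but intentionally not parsed here.
"""

from __future__ import annotations

from pathlib import Path

import trimesh

from .errors import UnsupportedFormatError
from .geometry import TriangleMesh

_SUPPORTED = {".off", ".obj"}


def read_mesh(path: str | Path) -> TriangleMesh:
    """Read an ASCII OFF or OBJ file into a :class:`TriangleMesh`."""
    path = Path(path)
    ext = path.suffix.lower()
    if ext in {".glb", ".gltf"}:
        raise UnsupportedFormatError(
            f"{path.name}: GLB/GLTF scene graphs are not parsed by this toolkit; "
            "export individual structures as OFF or OBJ"
        )
    if ext not in _SUPPORTED:
        raise UnsupportedFormatError(f"{path.name}: unsupported mesh format {ext!r} (use .off or .obj)")
    tm = trimesh.load(path, file_type=ext[1:], process=False, force="mesh")
    return TriangleMesh(tm.vertices.copy(), tm.faces.copy())


def write_mesh(mesh: TriangleMesh, path: str | Path) -> Path:
    """Write a mesh to ASCII OFF or OBJ, chosen by the file extension."""
    path = Path(path)
    ext = path.suffix.lower()
    if ext not in _SUPPORTED:
        raise UnsupportedFormatError(f"{path.name}: unsupported mesh format {ext!r} (use .off or .obj)")
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    tm.export(path, file_type=ext[1:])
    return path
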