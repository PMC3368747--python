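"""Isosurface extraction and mesh export for bone and hotspot boundaries.

The bone surface comes from the CT at a Hounsfield level (default +150) and
the hotspot boundary from the SPECT at the clinical threshold. Marching
cubes with linear edge interpolation (Lewiner variant, the scikit-image
default) produces the triangles; vertices are mapped through the volume
affine to world mm, or into an anatomic frame when one is given, so that
exported scenes are directly comparable between patients.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage import measure

from .frames import AnatomicFrame, world_to_anatomic
from .volume_io import ImageVolume

DEFAULT_BONE_LEVEL_HU = 150.0

_FORMATS = {"stl", "ply", "obj"}


@dataclass
class TriangleMesh:
    """Triangle mesh in mm; ``frame_tag`` records the coordinate frame."""

    vertices: np.ndarray  # (n, 3) float
    faces: np.ndarray  # (m, 3) int
    label: str = "bone"  # {"bone", "hotspot"}
    frame_tag: str = "world"

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=int).reshape(-1, 3)
        if len(self.faces):
            if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
                raise ValueError("face indices out of range")
            if np.any(
                (self.faces[:, 0] == self.faces[:, 1])
                | (self.faces[:, 1] == self.faces[:, 2])
                | (self.faces[:, 0] == self.faces[:, 2])
            ):
                raise ValueError("degenerate face repeats a vertex")

    @property
    def is_empty(self) -> bool:
        return len(self.faces) == 0

    def area_mm2(self) -> float:
        if self.is_empty:
            return 0.0
        v = self.vertices[self.faces]
        cross = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
        return float(0.5 * np.linalg.norm(cross, axis=1).sum())

    def enclosed_volume_mm3(self) -> float:
        """Signed volume by the divergence theorem (positive for outward
        consistently-oriented closed surfaces; absolute value returned)."""
        if self.is_empty:
            return 0.0
        v = self.vertices[self.faces]
        vol = np.einsum("ij,ij->i", v[:, 0], np.cross(v[:, 1], v[:, 2])).sum() / 6.0
        return float(abs(vol))


def extract_isosurface(
    vol: ImageVolume,
    level: float,
    frame: AnatomicFrame | None = None,
    label: str = "bone",
) -> TriangleMesh:
    """Marching-cubes isosurface at ``level``, vertices in mm.

    Returns an empty mesh when the level lies outside the data range.
    """
    if not np.isfinite(level):
        raise ValueError("isosurface level must be finite")
    data = np.asarray(vol.voxels, dtype=float)
    frame_tag = "world" if frame is None else frame.bone
    if not (data.min() < level < data.max()):
        return TriangleMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=int), label, frame_tag)
    verts_idx, faces, _normals, _vals = measure.marching_cubes(data, level=level)
    verts = verts_idx @ vol.affine[:3, :3].T + vol.affine[:3, 3]
    if frame is not None:
        verts = world_to_anatomic(verts, frame)
    return TriangleMesh(verts, faces, label=label, frame_tag=frame_tag)


def write_mesh(mesh: TriangleMesh, path: os.PathLike | str, fmt: str | None = None) -> None:
    """Export to STL, PLY or OBJ (via trimesh); format from ``fmt`` or extension."""
    import trimesh

    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt not in _FORMATS:
        raise ValueError(f"unknown mesh format {fmt!r} (use stl/ply/obj)")
    if mesh.is_empty and fmt == "stl":
        raise ValueError("cannot write an empty mesh to STL")
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    tm.export(str(path), file_type=fmt)


def read_mesh(path: os.PathLike | str, label: str = "bone", frame_tag: str = "world") -> TriangleMesh:
    import trimesh

    tm = trimesh.load_mesh(str(path), process=False)
    return TriangleMesh(np.asarray(tm.vertices), np.asarray(tm.faces), label, frame_tag)


def scene_export(bone: TriangleMesh, hotspot: TriangleMesh, path: os.PathLike | str) -> dict:
    """Write bone + hotspot meshes (PLY) plus a JSON manifest.

    Both meshes must share a coordinate frame. ``path`` is the manifest path;
    the meshes are written next to it as ``<stem>_bone.ply`` and
    ``<stem>_hotspot.ply``. Returns the manifest dict.
    """
    if bone.frame_tag != hotspot.frame_tag:
        raise ValueError(
            f"meshes are in different frames: {bone.frame_tag!r} vs {hotspot.frame_tag!r}"
        )
    path = Path(path)
    entries = []
    for mesh, name in ((bone, "bone"), (hotspot, "hotspot")):
        mesh_path = path.with_name(f"{path.stem}_{name}.ply")
        write_mesh(mesh, mesh_path, fmt="ply")
        entries.append(
            {
                "label": name,
                "file": mesh_path.name,
                "frame": mesh.frame_tag,
                "n_vertices": int(len(mesh.vertices)),
                "n_faces": int(len(mesh.faces)),
            }
        )
    manifest = {"meshes": entries}
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
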