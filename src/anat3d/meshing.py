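"""Mask-to-surface conversion and STL read/write.

Segmented structures are turned into triangle surfaces by marching
cubes on the binary field (level 0.5) and exported as stereolithography
(STL) files, the interchange format the downstream graphics engine
loads.  Masks are padded by one background voxel before extraction so
every surface is closed; vertices live in physical millimetres
(``index * spacing + origin``) and triangles are wound right-handed
with outward normals.

STL carries no colour: per-structure display colour lives in a sidecar
scene JSON (``[{"name", "stl_path", "color_rgb"}]``), see
:func:`write_scene_sidecar`.
"""

from __future__ import annotations

import json
import os
import re
import struct
from dataclasses import dataclass

import numpy as np
from skimage import measure

from .volume_io import Mask

__all__ = [
    "TriMesh",
    "MeshReport",
    "STLError",
    "extract_surface",
    "write_stl",
    "read_stl",
    "mesh_metrics",
    "write_scene_sidecar",
    "read_scene_sidecar",
]


class STLError(RuntimeError):
    """Raised for malformed or truncated STL files."""


@dataclass
class TriMesh:
    """Indexed triangle surface in physical mm.

    ``triangles`` are right-hand wound: the outward facet normal is
    ``cross(v1 - v0, v2 - v0)`` normalised.
    """

    vertices: np.ndarray  # (n, 3) float
    triangles: np.ndarray  # (m, 3) int
    name: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.triangles = np.asarray(self.triangles, dtype=np.int64).reshape(-1, 3)
        if not np.isfinite(self.vertices).all():
            raise ValueError("mesh vertices must be finite")
        if self.triangles.size:
            if self.triangles.min() < 0 or self.triangles.max() >= len(self.vertices):
                raise ValueError("triangle vertex index out of range")
            t = self.triangles
            if np.any((t[:, 0] == t[:, 1]) | (t[:, 1] == t[:, 2]) | (t[:, 0] == t[:, 2])):
                raise ValueError("degenerate triangle (repeated vertex index)")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def corners(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        v, t = self.vertices, self.triangles
        return v[t[:, 0]], v[t[:, 1]], v[t[:, 2]]

    def centroid(self) -> np.ndarray:
        """Mean vertex position (mm) — the pick target used for
        highlighting, not the volumetric barycentre."""
        return self.vertices.mean(axis=0)

    def flipped(self) -> "TriMesh":
        """Same surface with reversed winding (normals negated)."""
        return TriMesh(self.vertices.copy(), self.triangles[:, [0, 2, 1]].copy(), self.name)


@dataclass
class MeshReport:
    n_vertices: int
    n_triangles: int
    watertight: bool
    surface_area: float  # mm^2
    enclosed_volume: float  # mm^3, signed; meaningful when watertight


def extract_surface(mask: Mask, iso: float = 0.5) -> TriMesh:
    """Marching-cubes surface of a binary mask, in physical mm.

    The mask is padded with one layer of background so the surface is
    closed even when the structure touches the grid border; ``iso`` is
    the level on the 0/1 field, 0.5 by default.
    """
    if not (0.0 < iso < 1.0):
        raise ValueError(f"iso must be in (0, 1), got {iso}")
    if not mask.data.any():
        raise ValueError("cannot extract a surface from an empty mask")
    padded = np.pad(mask.data, 1).astype(np.float32)
    verts, faces, _, _ = measure.marching_cubes(padded, level=iso, spacing=mask.spacing)
    # undo the pad shift, then map to physical coordinates
    verts = verts - np.asarray(mask.spacing) + np.asarray(mask.origin)
    # skimage's winding is inward under the right-hand rule; flip for
    # outward normals / positive divergence-theorem volume.
    faces = faces[:, [0, 2, 1]]
    return TriMesh(vertices=verts, triangles=faces)


def _facet_normals(mesh: TriMesh) -> np.ndarray:
    v0, v1, v2 = mesh.corners()
    n = np.cross(v1 - v0, v2 - v0)
    lengths = np.linalg.norm(n, axis=1)
    nz = lengths > 0
    n[nz] /= lengths[nz, None]
    return n


def write_stl(mesh: TriMesh, path: str | os.PathLike, mode: str = "binary") -> None:
    """Write STL.  Binary layout: 80-byte header, uint32 facet count,
    then 50 bytes per facet (normal + 3 vertices as float32 triples +
    uint16 attribute), little-endian.  ASCII uses the standard
    solid/facet grammar.  Facet normals are recomputed from the
    right-hand vertex order."""
    if mode not in ("binary", "ascii"):
        raise ValueError(f"mode must be 'binary' or 'ascii', got {mode!r}")
    path = os.fspath(path)
    normals = _facet_normals(mesh).astype(np.float32)
    v0, v1, v2 = (c.astype(np.float32) for c in mesh.corners())
    if mode == "binary":
        rec = np.zeros(
            mesh.n_triangles,
            dtype=np.dtype(
                [("normal", "<f4", 3), ("v0", "<f4", 3), ("v1", "<f4", 3),
                 ("v2", "<f4", 3), ("attr", "<u2")]
            ),
        )
        rec["normal"], rec["v0"], rec["v1"], rec["v2"] = normals, v0, v1, v2
        header = (mesh.name or "anat3d mesh").encode()[:80].ljust(80, b"\0")
        try:
            with open(path, "wb") as fh:
                fh.write(header)
                fh.write(struct.pack("<I", mesh.n_triangles))
                fh.write(rec.tobytes())
        except OSError as exc:
            raise STLError(f"cannot write {path!r}: {exc}") from exc
    else:
        name = mesh.name or "anat3d_mesh"
        lines = [f"solid {name}"]
        for i in range(mesh.n_triangles):
            nx, ny, nz = normals[i]
            lines.append(f"  facet normal {nx:e} {ny:e} {nz:e}")
            lines.append("    outer loop")
            for corner in (v0[i], v1[i], v2[i]):
                lines.append(f"      vertex {corner[0]:e} {corner[1]:e} {corner[2]:e}")
            lines.append("    endloop")
            lines.append("  endfacet")
        lines.append(f"endsolid {name}\n")
        try:
            with open(path, "w") as fh:
                fh.write("\n".join(lines))
        except OSError as exc:
            raise STLError(f"cannot write {path!r}: {exc}") from exc


def _soup_to_mesh(tri_corners: np.ndarray, name: str) -> TriMesh:
    """Deduplicate a (m, 3, 3) float32 triangle soup by exact coordinate
    match and build an indexed mesh."""
    flat = tri_corners.reshape(-1, 3).astype(np.float32)
    uniq, inverse = np.unique(flat, axis=0, return_inverse=True)
    triangles = inverse.reshape(-1, 3)
    return TriMesh(vertices=uniq.astype(float), triangles=triangles, name=name)


_ASCII_VERTEX = re.compile(
    rb"vertex\s+([-+0-9.eE]+)\s+([-+0-9.eE]+)\s+([-+0-9.eE]+)"
)


def read_stl(path: str | os.PathLike) -> TriMesh:
    """Read a binary or ASCII STL file (dialect auto-detected).

    Vertices are deduplicated by exact float32 coordinate match; the
    triangle count is preserved.  Truncated binary payloads raise
    :class:`STLError` naming the expected and actual size.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise STLError(f"STL file not found: {path!r}")
    with open(path, "rb") as fh:
        blob = fh.read()
    if len(blob) >= 84:
        (count,) = struct.unpack_from("<I", blob, 80)
        expected = 84 + 50 * count
        if len(blob) == expected:
            rec = np.frombuffer(
                blob, offset=84, count=count,
                dtype=np.dtype(
                    [("normal", "<f4", 3), ("v0", "<f4", 3), ("v1", "<f4", 3),
                     ("v2", "<f4", 3), ("attr", "<u2")]
                ),
            )
            soup = np.stack([rec["v0"], rec["v1"], rec["v2"]], axis=1)
            name = blob[:80].rstrip(b"\0").decode(errors="replace").strip()
            return _soup_to_mesh(soup, name)
        if not blob.lstrip().startswith(b"solid"):
            raise STLError(
                f"truncated binary STL {path!r}: header declares {count} facets "
                f"({expected} bytes expected) but file has {len(blob)} bytes"
            )
    if blob.lstrip().startswith(b"solid"):
        coords = _ASCII_VERTEX.findall(blob)
        if len(coords) == 0 or len(coords) % 3 != 0:
            raise STLError(f"malformed ASCII STL {path!r}: {len(coords)} vertex lines")
        soup = np.array(coords, dtype=np.float32).reshape(-1, 3, 3)
        first = blob.lstrip().splitlines()[0]
        name = first[5:].strip().decode(errors="replace")
        return _soup_to_mesh(soup, name)
    raise STLError(f"{path!r} is neither valid binary nor ASCII STL")


def mesh_metrics(mesh: TriMesh) -> MeshReport:
    """Counts, watertightness (every undirected edge shared by exactly
    two triangles), surface area and signed divergence-theorem volume."""
    v0, v1, v2 = mesh.corners()
    cross = np.cross(v1 - v0, v2 - v0)
    area = float(np.linalg.norm(cross, axis=1).sum() / 2.0)
    volume = float(np.einsum("ij,ij->", np.cross(v0, v1), v2) / 6.0)
    t = mesh.triangles
    edges = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
    edges = np.sort(edges, axis=1)
    if len(edges):
        _, counts = np.unique(edges, axis=0, return_counts=True)
        watertight = bool(np.all(counts == 2))
    else:
        watertight = False
    return MeshReport(
        n_vertices=mesh.n_vertices,
        n_triangles=mesh.n_triangles,
        watertight=watertight,
        surface_area=area,
        enclosed_volume=volume,
    )


def write_scene_sidecar(entries: list[dict], path: str | os.PathLike) -> None:
    """Write the scene sidecar JSON: a list of
    ``{"name", "stl_path", "color_rgb"}`` records."""
    for e in entries:
        missing = {"name", "stl_path", "color_rgb"} - set(e)
        if missing:
            raise ValueError(f"scene entry {e} missing keys {sorted(missing)}")
    with open(os.fspath(path), "w") as fh:
        json.dump(entries, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_scene_sidecar(path: str | os.PathLike) -> list[dict]:
    with open(os.fspath(path)) as fh:
        entries = json.load(fh)
    if not isinstance(entries, list):
        raise ValueError("scene sidecar must be a JSON list")
    return entries
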