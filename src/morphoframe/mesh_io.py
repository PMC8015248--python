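"""Triangle-mesh I/O, validation, and normalization.

The shape observation at one time point is a closed genus-0 triangulated
surface. The cell's position is summarized by the mass center, defined as
the unweighted arithmetic mean of the vertices (not the volumetric
centroid); for spherical-harmonic analysis every mesh is rescaled to unit
enclosed volume so that shape descriptors are size-free.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import trimesh

from morphoframe.errors import (
    MeshFormatError,
    OrientationError,
    UnsupportedTopologyError,
)

logger = logging.getLogger(__name__)

_SUPPORTED_FORMATS = {"obj", "ply", "off"}


@dataclass
class TriangleMesh:
    """A triangulated surface at one time point.

    Parameters
    ----------
    vertices : (V, 3) float array
        Vertex coordinates; length units are arbitrary but consistent.
    faces : (F, 3) int array
        Triangles as vertex-index triples.
    time_index : int
        Integer time stamp of the observation.
    """

    vertices: np.ndarray
    faces: np.ndarray
    time_index: int = 0

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be an (V, 3) array")
        if self.faces.size and (self.faces.ndim != 2 or self.faces.shape[1] != 3):
            raise UnsupportedTopologyError("faces must be an (F, 3) array of triangles")
        if self.faces.size:
            if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
                raise ValueError("face indices out of range")
            if np.any(
                (self.faces[:, 0] == self.faces[:, 1])
                | (self.faces[:, 1] == self.faces[:, 2])
                | (self.faces[:, 0] == self.faces[:, 2])
            ):
                raise UnsupportedTopologyError("degenerate face with repeated vertex")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces.copy(), self.time_index)


def read_mesh(path: str | Path, fmt: str | None = None, time_index: int = 0) -> TriangleMesh:
    """Read an OBJ/PLY/OFF file into a :class:`TriangleMesh`.

    Vertices and faces are kept exactly as stored (no merging or
    reordering). Non-triangular faces raise
    :class:`~morphoframe.errors.UnsupportedTopologyError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt not in _SUPPORTED_FORMATS:
        raise MeshFormatError(f"unsupported mesh format: {fmt!r}")
    try:
        raw = trimesh.load(
            str(path), file_type=fmt, process=False, force="mesh", maintain_order=True
        )
    except UnsupportedTopologyError:
        raise
    except Exception as exc:  # trimesh raises heterogeneous parse errors
        raise MeshFormatError(f"could not parse {path} as {fmt}: {exc}") from exc
    if not isinstance(raw, trimesh.Trimesh) or len(raw.faces) == 0:
        raise MeshFormatError(f"{path} contains no triangulated surface")
    # trimesh silently triangulates quads; detect them from the raw file text
    if fmt in ("obj", "off") and _has_nontriangular_faces(path, fmt):
        raise UnsupportedTopologyError(f"{path} contains non-triangular faces")
    return TriangleMesh(np.asarray(raw.vertices, float), np.asarray(raw.faces), time_index)


def _has_nontriangular_faces(path: Path, fmt: str) -> bool:
    text = path.read_text().splitlines()
    if fmt == "obj":
        for line in text:
            if line.startswith("f ") and len(line.split()) - 1 != 3:
                return True
        return False
    # OFF: header line "OFF", then "V F E", then V vertex lines, then faces
    lines = [ln.split("#")[0].strip() for ln in text]
    lines = [ln for ln in lines if ln]
    if not lines or not lines[0].upper().startswith("OFF"):
        return False
    header = lines[1].split() if lines[0].strip().upper() == "OFF" else lines[0][3:].split()
    start = 2 if lines[0].strip().upper() == "OFF" else 1
    n_v, n_f = int(header[0]), int(header[1])
    for ln in lines[start + n_v : start + n_v + n_f]:
        if int(ln.split()[0]) != 3:
            return True
    return False


def write_mesh(mesh: TriangleMesh, path: str | Path, fmt: str | None = None) -> Path:
    """Write a mesh as OBJ, PLY (ascii), or OFF at full float precision."""
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt not in _SUPPORTED_FORMATS:
        raise MeshFormatError(f"unsupported mesh format: {fmt!r}")
    v, f = mesh.vertices, mesh.faces
    lines: list[str] = []
    if fmt == "obj":
        lines += [f"v {x:.17g} {y:.17g} {z:.17g}" for x, y, z in v]
        lines += [f"f {a + 1} {b + 1} {c + 1}" for a, b, c in f]
    elif fmt == "off":
        lines += ["OFF", f"{len(v)} {len(f)} 0"]
        lines += [f"{x:.17g} {y:.17g} {z:.17g}" for x, y, z in v]
        lines += [f"3 {a} {b} {c}" for a, b, c in f]
    else:  # ascii PLY
        lines += [
            "ply",
            "format ascii 1.0",
            f"element vertex {len(v)}",
            "property double x",
            "property double y",
            "property double z",
            f"element face {len(f)}",
            "property list uchar int vertex_indices",
            "end_header",
        ]
        lines += [f"{x:.17g} {y:.17g} {z:.17g}" for x, y, z in v]
        lines += [f"3 {a} {b} {c}" for a, b, c in f]
    path.write_text("\n".join(lines) + "\n")
    return path


def check_spherical_topology(mesh: TriangleMesh) -> bool:
    """True iff the mesh is closed and topologically a sphere.

    Checks that every edge is shared by exactly two faces and that the
    Euler characteristic V - E + F equals 2. Meshes failing this cannot be
    spherically parameterized and are excluded from analysis.
    """
    if mesh.n_faces == 0:
        return False
    edges = np.sort(
        np.concatenate(
            [mesh.faces[:, [0, 1]], mesh.faces[:, [1, 2]], mesh.faces[:, [2, 0]]]
        ),
        axis=1,
    )
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    if not np.all(counts == 2):
        return False
    n_e = len(uniq)
    used = np.unique(mesh.faces)
    n_v = len(used)
    return n_v - n_e + mesh.n_faces == 2


def mass_center(mesh: TriangleMesh) -> np.ndarray:
    """Arithmetic mean of the vertex coordinates.

    This is the trajectory observation: the componentwise unweighted mean
    of the vertices, deliberately not the area- or volume-weighted
    centroid.
    """
    if mesh.n_vertices == 0:
        raise ValueError("mesh has no vertices")
    return mesh.vertices.mean(axis=0)


def volumetric_centroid(mesh: TriangleMesh) -> np.ndarray:
    """Center of mass of the enclosed solid (optional alternative)."""
    tm = trimesh.Trimesh(mesh.vertices, mesh.faces, process=False)
    return np.asarray(tm.center_mass, float)


def signed_volume(mesh: TriangleMesh) -> float:
    """Enclosed signed volume by the divergence theorem over triangles.

    Positive for outward-facing winding of a closed surface.
    """
    v0 = mesh.vertices[mesh.faces[:, 0]]
    v1 = mesh.vertices[mesh.faces[:, 1]]
    v2 = mesh.vertices[mesh.faces[:, 2]]
    return float(np.einsum("ij,ij->i", v0, np.cross(v1, v2)).sum() / 6.0)


def normalize_volume(mesh: TriangleMesh, rtol: float = 1e-6) -> TriangleMesh:
    """Uniformly scale the mesh about its mass center to unit volume.

    Raises :class:`~morphoframe.errors.OrientationError` when the signed
    volume is non-positive: that indicates inward-facing winding, which is
    reported rather than silently flipped.
    """
    vol = signed_volume(mesh)
    if vol <= 0:
        raise OrientationError(
            f"signed volume {vol:.3g} is non-positive; "
            "check face winding (flipping all faces may fix it)"
        )
    if abs(vol - 1.0) <= rtol:
        return mesh.copy()
    center = mass_center(mesh)
    scale = vol ** (-1.0 / 3.0)
    out = TriangleMesh(center + (mesh.vertices - center) * scale, mesh.faces.copy(), mesh.time_index)
    assert abs(signed_volume(out) - 1.0) < 1e-6
    return out
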