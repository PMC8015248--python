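"""Shared fixtures: canonical meshes and trajectories, built in memory."""

import numpy as np
import pytest
import trimesh

from morphoframe.mesh_io import TriangleMesh, normalize_volume

UNIT_VOLUME_RADIUS = (3.0 / (4.0 * np.pi)) ** (1.0 / 3.0)


@pytest.fixture
def icosahedron() -> TriangleMesh:
    ico = trimesh.creation.icosahedron()
    return TriangleMesh(np.asarray(ico.vertices, float), np.asarray(ico.faces))


@pytest.fixture
def icosphere_factory():
    """factory(subdivisions, radius) -> TriangleMesh."""

    def make(subdivisions: int = 3, radius: float = 1.0) -> TriangleMesh:
        ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
        return TriangleMesh(np.asarray(ico.vertices, float), np.asarray(ico.faces))

    return make


@pytest.fixture
def ellipsoid_factory():
    """factory(rx, ry, rz, subdivisions) -> unit-volume axis-aligned ellipsoid."""

    def make(rx: float, ry: float = 1.0, rz: float = 1.0, subdivisions: int = 3) -> TriangleMesh:
        ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
        a = (1.0 / (rx * ry * rz)) ** (1.0 / 3.0) * UNIT_VOLUME_RADIUS
        verts = np.asarray(ico.vertices, float) * (a * np.array([rx, ry, rz]))
        return normalize_volume(TriangleMesh(verts, np.asarray(ico.faces)))

    return make


@pytest.fixture
def torus_mesh() -> TriangleMesh:
    tor = trimesh.creation.torus(major_radius=2.0, minor_radius=0.5)
    return TriangleMesh(np.asarray(tor.vertices, float), np.asarray(tor.faces))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
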