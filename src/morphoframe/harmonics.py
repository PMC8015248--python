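"""Real spherical-harmonic shape descriptors.

Each Cartesian coordinate function of the spherically parameterized
surface is expanded in orthonormal real spherical harmonics (no
Condon-Shortley phase):

    x(theta, phi) ~= sum_{l=0}^{l_max} sum_{m=-l}^{l} C_x(l, m) Y_lm(theta, phi)

with Y_lm built from associated Legendre polynomials; the coefficients are
found by unweighted linear least squares over the mesh vertices. The
coefficient vectors for x, y, z are concatenated into one descriptor
C = (C_x, C_y, C_z) of length 3 (l_max + 1)^2. Flat indexing within each
coordinate follows j = l^2 + l + m + 1 (1-based).

The expansion uses the polar axis along +y (colatitude arccos(y), azimuth
atan2(z, x)) so that the degree-1 harmonics (1,1), (1,0), (1,-1) are
proportional to x, y, z respectively. The degree-1 coefficients
C_x(1,1), C_y(1,0), C_z(1,-1) therefore measure extent along the x, y, z
axes, and their ratios

    E_xy = C_x(1,1) / C_y(1,0),  E_xz = C_x(1,1) / C_z(1,-1),
    E_yz = C_y(1,0) / C_z(1,-1)

are eccentricity indices: all 1 for a perfect sphere, and equal to the
semi-axis ratios for an axis-aligned ellipsoid. E_yz = E_xz / E_xy is
redundant given the other two.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import sph_harm_y

from morphoframe.errors import DegenerateShapeError, IncompatibleDescriptorError
from morphoframe.mesh_io import TriangleMesh
from morphoframe.spherical_param import SphericalMap, angles_to_unit_vectors

logger = logging.getLogger(__name__)


def sh_index(l: int, m: int) -> int:
    """1-based flat index j = l^2 + l + m + 1 of harmonic (l, m)."""
    if not (0 <= l and -l <= m <= l):
        raise ValueError(f"invalid order m={m} for degree l={l}")
    return l * l + l + m + 1


def sh_degree_order(j: int) -> tuple[int, int]:
    """Inverse of :func:`sh_index`."""
    if j < 1:
        raise ValueError("index is 1-based")
    l = int(np.floor(np.sqrt(j - 1)))
    m = j - 1 - l * l - l
    return l, m


def real_sh(l: int, m: int, theta, phi) -> np.ndarray:
    """Orthonormal real spherical harmonic without Condon-Shortley phase.

    m > 0 pairs with cos(m phi), m < 0 with sin(|m| phi), m = 0 is zonal;
    all normalized to unit L2 norm on the sphere.
    """
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    am = abs(m)
    # scipy's complex Y includes the Condon-Shortley phase; (-1)^m removes it
    Y = sph_harm_y(l, am, theta, phi) * (-1.0) ** am
    if m > 0:
        return np.sqrt(2.0) * np.real(Y)
    if m < 0:
        return np.sqrt(2.0) * np.imag(Y)
    return np.real(Y)


def unit_vectors_to_basis_angles(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Colatitude/azimuth of unit vectors in the basis (y-pole) convention.

    theta = arccos(y) in [0, pi], phi = atan2(z, x) in [-pi, pi). With
    this pole choice the degree-1 harmonics align with the coordinate
    axes as x <-> (1,1), y <-> (1,0), z <-> (1,-1), which is what the
    eccentricity indices assume.
    """
    v = np.asarray(v, dtype=float)
    theta = np.arccos(np.clip(v[:, 1], -1.0, 1.0))
    phi = np.arctan2(v[:, 2], v[:, 0])
    return theta, phi


@dataclass
class SHBasis:
    """Truncated orthonormal real SH basis (Condon-Shortley off)."""

    l_max: int = 6

    def __post_init__(self):
        if self.l_max < 0:
            raise ValueError("l_max must be non-negative")

    @property
    def size(self) -> int:
        """Number of basis functions k = (l_max + 1)^2."""
        return (self.l_max + 1) ** 2

    def design_matrix(self, theta, phi) -> np.ndarray:
        """(n, k) matrix with column j-1 holding Y_lm at each sample."""
        theta = np.asarray(theta, dtype=float)
        cols = np.empty((len(theta), self.size))
        for l in range(self.l_max + 1):
            for m in range(-l, l + 1):
                cols[:, sh_index(l, m) - 1] = real_sh(l, m, theta, phi)
        return cols


@dataclass
class SHCoefficients:
    """Fitted real-SH coefficients of the three coordinate functions."""

    c_x: np.ndarray
    c_y: np.ndarray
    c_z: np.ndarray
    l_max: int
    residual_rms: float = float("nan")

    @property
    def combined(self) -> np.ndarray:
        """Concatenated shape descriptor C = (C_x, C_y, C_z), length 3k."""
        return np.concatenate([self.c_x, self.c_y, self.c_z])

    def coefficient(self, coord: str, l: int, m: int) -> float:
        vec = {"x": self.c_x, "y": self.c_y, "z": self.c_z}[coord]
        return float(vec[sh_index(l, m) - 1])


@dataclass
class EccentricityIndices:
    """Pairwise elongation ratios from the degree-1 coefficients."""

    E_xy: float
    E_xz: float
    E_yz: float


def fit_coefficients(
    smap: SphericalMap, basis: SHBasis | None = None, area_weighted: bool = False
) -> SHCoefficients:
    """Least-squares SH expansion of the surface coordinate functions.

    Solves the (n_vertices x k) linear system ``Y c = coord`` for each of
    x, y, z over the spherical parameterization's angles. Requires
    n_vertices >= k. ``area_weighted=True`` weights rows by Voronoi-ish
    vertex areas of the source mesh to counter parameterization area
    distortion (off by default).
    """
    basis = basis or SHBasis()
    theta, phi = unit_vectors_to_basis_angles(smap.sphere_vertices)
    n, k = len(theta), basis.size
    if n < k:
        raise ValueError(f"underdetermined fit: {n} vertices < {k} basis functions")
    Y = basis.design_matrix(theta, phi)
    coords = smap.mesh.vertices
    if area_weighted:
        w = np.sqrt(_vertex_areas(smap.mesh))
        Y = Y * w[:, None]
        coords = coords * w[:, None]
    sol, res, rank, _ = np.linalg.lstsq(Y, coords, rcond=None)
    if rank < k:
        warnings.warn("rank-deficient SH design matrix; minimum-norm solution used")
    resid = Y @ sol - coords
    rms = float(np.sqrt(np.mean(resid**2)))
    return SHCoefficients(sol[:, 0], sol[:, 1], sol[:, 2], basis.l_max, rms)


def _vertex_areas(mesh: TriangleMesh) -> np.ndarray:
    v0, v1, v2 = (mesh.vertices[mesh.faces[:, k]] for k in range(3))
    area = 0.5 * np.linalg.norm(np.cross(v1 - v0, v2 - v0), axis=1)
    out = np.zeros(mesh.n_vertices)
    for k in range(3):
        np.add.at(out, mesh.faces[:, k], area / 3.0)
    return out


def eccentricities(coeffs: SHCoefficients, eps: float = 1e-12) -> EccentricityIndices:
    """Eccentricity indices from the degree-1 coefficient magnitudes.

    Absolute values are used: the coefficient signs depend on the
    parameterization's pole alignment and carry no shape information.
    """
    cx = abs(coeffs.coefficient("x", 1, 1))
    cy = abs(coeffs.coefficient("y", 1, 0))
    cz = abs(coeffs.coefficient("z", 1, -1))
    if cy < eps or cz < eps:
        raise DegenerateShapeError("degree-1 denominator coefficient is ~zero")
    return EccentricityIndices(E_xy=cx / cy, E_xz=cx / cz, E_yz=cy / cz)


def shape_distance(a: SHCoefficients, b: SHCoefficients) -> float:
    """L2 distance between two concatenated SH descriptors."""
    if a.l_max != b.l_max:
        raise IncompatibleDescriptorError(
            f"descriptors have l_max {a.l_max} vs {b.l_max}"
        )
    return float(np.linalg.norm(a.combined - b.combined))


def shape_change_rate(series: list[SHCoefficients]) -> np.ndarray:
    """Shape-change rate d(t, t+1) between consecutive descriptors."""
    if len(series) < 2:
        raise ValueError("need at least 2 time points")
    return np.array([shape_distance(a, b) for a, b in zip(series[:-1], series[1:])])


def reconstruct_surface(
    coeffs: SHCoefficients, theta: np.ndarray, phi: np.ndarray, faces: np.ndarray | None = None
) -> TriangleMesh:
    """Evaluate the truncated SH series on a (theta, phi) sample set.

    Used for visualization and round-trip testing; ``faces`` defaults to
    an empty list, producing a point cloud wrapped as a mesh.
    """
    basis = SHBasis(coeffs.l_max)
    Y = basis.design_matrix(np.asarray(theta, float), np.asarray(phi, float))
    verts = np.column_stack([Y @ coeffs.c_x, Y @ coeffs.c_y, Y @ coeffs.c_z])
    if faces is None:
        faces = np.empty((0, 3), dtype=np.int64)
    return TriangleMesh(verts, faces)
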