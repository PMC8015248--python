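"""Parallel-transport moving frames along a smooth trajectory.

A moving frame is an orthonormal right-handed triad (T, N, B) attached to
each trajectory sample: T is the unit velocity, N a normal carried along
the curve by parallel transport (rotating only as much as the tangent
turns, so the frame carries no spurious twist, unlike the Frenet frame),
and B = T x N. Expressing each surface mesh in this basis makes the
velocity direction the new x-axis, which renders downstream shape
descriptors invariant to rigid motions of the scene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from morphoframe.errors import StationaryCellError
from morphoframe.mesh_io import TriangleMesh
from morphoframe.trajectory import SmoothTrajectory

logger = logging.getLogger(__name__)

#: threshold on ||T_i x T_{i+1}|| below which consecutive tangents count as parallel
EPS_PARALLEL = 1e-10


@dataclass
class Frame:
    """Orthonormal right-handed triad at one trajectory point."""

    T: np.ndarray
    N: np.ndarray
    B: np.ndarray
    origin: np.ndarray

    def matrix(self) -> np.ndarray:
        """Rotation matrix with rows T, N, B (world -> frame coordinates)."""
        return np.stack([self.T, self.N, self.B])

    def is_valid(self, tol: float = 1e-9) -> bool:
        M = self.matrix()
        return (
            np.allclose(M @ M.T, np.eye(3), atol=tol)
            and abs(np.linalg.det(M) - 1.0) < tol
            and np.allclose(self.B, np.cross(self.T, self.N), atol=tol)
        )


@dataclass
class FrameSequence:
    """Time-ordered frames, one per dense trajectory sample."""

    times: np.ndarray
    frames: list[Frame]

    def __len__(self) -> int:
        return len(self.frames)

    def at_time(self, t: float) -> Frame:
        idx = int(np.argmin(np.abs(self.times - t)))
        if abs(self.times[idx] - t) > 1e-9 * max(1.0, abs(t)):
            raise KeyError(f"no frame at time {t}")
        return self.frames[idx]


def tangent_vectors(smooth: SmoothTrajectory, speed_threshold: float = 1e-12) -> np.ndarray:
    """Unit tangents from finite-difference velocities.

    At samples where the speed is ~zero the previous tangent is carried
    forward (and the first defined tangent is back-filled to the start).
    A trajectory with zero velocity everywhere raises
    :class:`~morphoframe.errors.StationaryCellError`.
    """
    if len(smooth.times) < 2:
        raise ValueError("need at least 2 points")
    vel = np.gradient(smooth.points, smooth.times, axis=0)
    norms = np.linalg.norm(vel, axis=1)
    moving = norms > speed_threshold
    if not moving.any():
        raise StationaryCellError("zero velocity over the whole trajectory")
    T = np.zeros_like(vel)
    T[moving] = vel[moving] / norms[moving, None]
    first = int(np.argmax(moving))
    T[:first] = T[first]
    for i in range(first + 1, len(T)):
        if not moving[i]:
            T[i] = T[i - 1]
    return T


def initial_normal(T0: np.ndarray) -> np.ndarray:
    """Deterministic unit normal perpendicular to the first tangent.

    Takes the coordinate axis least aligned with T0 and Gram-Schmidts it
    against T0; reproducible, with no arbitrary sign freedom.
    """
    T0 = np.asarray(T0, dtype=float)
    if np.linalg.norm(T0) < 1e-12:
        raise ValueError("zero tangent vector")
    T0 = T0 / np.linalg.norm(T0)
    axis = np.zeros(3)
    axis[int(np.argmin(np.abs(T0)))] = 1.0
    N0 = axis - (axis @ T0) * T0
    return N0 / np.linalg.norm(N0)


def rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if abs(norm - 1.0) > 1e-6:
        raise ValueError(f"axis must be unit length (got norm {norm:.3g})")
    if abs(norm - 1.0) > 1e-9:
        logger.warning("normalizing near-unit rotation axis (norm %.3g)", norm)
    axis = axis / norm
    K = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    return np.eye(3) + np.sin(angle) * K + (1.0 - np.cos(angle)) * (K @ K)


def _transport_normal(N: np.ndarray, T_cur: np.ndarray, T_next: np.ndarray) -> np.ndarray:
    """Carry a normal across one tangent step with minimal rotation."""
    U = np.cross(T_cur, T_next)
    nU = np.linalg.norm(U)
    dot = float(np.clip(T_cur @ T_next, -1.0, 1.0))
    if nU < EPS_PARALLEL:
        if dot < 0.0:
            # tangent reversal: compose two half-turns about a perpendicular axis
            logger.warning("antiparallel consecutive tangents; applying reversal rotation")
            axis = initial_normal(T_cur)
            R = rotation_matrix(axis, np.pi / 2.0)
            return R @ (R @ N)
        return N
    theta = np.arccos(dot)
    return rotation_matrix(U / nU, theta) @ N


def parallel_transport_frames(
    smooth: SmoothTrajectory, N0: np.ndarray | None = None
) -> FrameSequence:
    """Build the parallel-transport frame at every dense trajectory sample.

    N_{i+1} is N_i rotated about U_i = T_i x T_{i+1} by the tangent turn
    angle theta_i = arccos(T_i . T_{i+1}); when consecutive tangents are
    parallel the normal is copied unchanged. B_i = T_i x N_i completes the
    right-handed triad.
    """
    T = tangent_vectors(smooth)
    if N0 is None:
        N = initial_normal(T[0])
    else:
        N = np.asarray(N0, dtype=float)
        N = N - (N @ T[0]) * T[0]
        nn = np.linalg.norm(N)
        if nn < 1e-9:
            raise ValueError("supplied N0 is parallel to the first tangent")
        N = N / nn
    frames = []
    for i in range(len(T)):
        if i > 0:
            N = _transport_normal(N, T[i - 1], T[i])
            # re-orthogonalize against accumulated numerical drift
            N = N - (N @ T[i]) * T[i]
            N = N / np.linalg.norm(N)
        if np.any(~np.isfinite(T[i])) or np.any(~np.isfinite(N)):
            raise ValueError(f"non-finite frame at sample {i}")
        B = np.cross(T[i], N)
        frames.append(Frame(T[i].copy(), N.copy(), B, smooth.points[i].copy()))
    return FrameSequence(smooth.times.copy(), frames)


def identity_frames(smooth: SmoothTrajectory) -> FrameSequence:
    """Standard-basis frames (no realignment), for the ablation baseline."""
    eye = np.eye(3)
    frames = [
        Frame(eye[0].copy(), eye[1].copy(), eye[2].copy(), p.copy()) for p in smooth.points
    ]
    return FrameSequence(smooth.times.copy(), frames)


def reorient_mesh(mesh: TriangleMesh, frame: Frame) -> TriangleMesh:
    """Express mesh vertices in the moving-frame basis.

    Each vertex v maps to v* = M (v - origin) with M the frame's rotation
    matrix, so the motion direction becomes the new x-axis. Faces are
    unchanged; the map is an isometry.
    """
    if not frame.is_valid(tol=1e-6):
        raise ValueError("frame is not an orthonormal right-handed triad")
    verts = (mesh.vertices - frame.origin) @ frame.matrix().T
    return TriangleMesh(verts, mesh.faces.copy(), mesh.time_index)
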