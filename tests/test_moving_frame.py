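import numpy as np
import pytest

from morphoframe.errors import StationaryCellError
from morphoframe.mesh_io import TriangleMesh
from morphoframe.moving_frame import (
    Frame,
    identity_frames,
    initial_normal,
    parallel_transport_frames,
    reorient_mesh,
    rotation_matrix,
    tangent_vectors,
)
from morphoframe.trajectory import SmoothTrajectory


def analytic_trajectory(times, points) -> SmoothTrajectory:
    times = np.asarray(times, float)
    return SmoothTrajectory(times, np.asarray(points, float), np.zeros(3), np.ones(3), times)


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


class TestTangents:
    def test_straight_line(self):
        t = np.arange(0.0, 5.0, 0.5)
        T = tangent_vectors(analytic_trajectory(t, np.column_stack([t, 0 * t, 0 * t])))
        np.testing.assert_allclose(T, np.tile([1.0, 0, 0], (len(t), 1)), atol=1e-12)

    def test_circle_tangent_unit_and_tangential(self):
        t = np.linspace(0, 2 * np.pi, 400)
        pos = np.column_stack([np.cos(t), np.sin(t), 0 * t])
        T = tangent_vectors(analytic_trajectory(t, pos))
        np.testing.assert_allclose(np.linalg.norm(T, axis=1), 1.0, atol=1e-9)
        # tangent orthogonal to radius (interior; ends use one-sided differences)
        np.testing.assert_allclose(
            np.einsum("ij,ij->i", T, pos)[1:-1], 0.0, atol=1e-3
        )

    def test_repeated_point_carries_tangent_forward(self):
        t = np.arange(6.0)
        pos = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [2, 0, 0], [2, 0, 0], [3, 0, 0.0]])
        # central differences put zero velocity at the middle repeat
        T = tangent_vectors(analytic_trajectory(t, pos))
        np.testing.assert_allclose(T[3], T[2], atol=1e-12)

    def test_stationary_trajectory_is_an_error(self):
        t = np.arange(5.0)
        with pytest.raises(StationaryCellError):
            tangent_vectors(analytic_trajectory(t, np.zeros((5, 3))))


class TestInitialNormal:
    def test_least_aligned_axis_rule(self):
        np.testing.assert_allclose(initial_normal([1.0, 0, 0]), [0, 1, 0], atol=1e-12)

    @pytest.mark.parametrize(
        "T0", [[0.0, 0, 1], [0.6, 0.8, 0], [1 / np.sqrt(3)] * 3, [-0.2, 0.5, 0.84]]
    )
    def test_orthogonal_unit(self, T0):
        T0 = np.asarray(T0) / np.linalg.norm(T0)
        N0 = initial_normal(T0)
        assert abs(N0 @ T0) < 1e-12
        assert abs(np.linalg.norm(N0) - 1.0) < 1e-12

    def test_zero_tangent_rejected(self):
        with pytest.raises(ValueError):
            initial_normal([0.0, 0.0, 0.0])


class TestRotationMatrix:
    def test_zero_angle_is_identity(self):
        np.testing.assert_allclose(rotation_matrix([0, 0, 1.0], 0.0), np.eye(3), atol=1e-15)

    def test_quarter_turn(self):
        R = rotation_matrix([0, 0, 1.0], np.pi / 2)
        np.testing.assert_allclose(R @ [1, 0, 0], [0, 1, 0], atol=1e-12)

    def test_inverse(self, rng):
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        R = rotation_matrix(u, 0.7) @ rotation_matrix(u, -0.7)
        np.testing.assert_allclose(R, np.eye(3), atol=1e-12)

    def test_non_unit_axis_rejected(self):
        with pytest.raises(ValueError):
            rotation_matrix([0, 0, 2.0], 0.3)


class TestParallelTransport:
    def test_straight_line_constant_frame(self):
        t = np.arange(0.0, 10.0)
        fs = parallel_transport_frames(
            analytic_trajectory(t, np.column_stack([t, t, 0 * t]))
        )
        first = fs.frames[0]
        for f in fs.frames:
            np.testing.assert_allclose(f.T, first.T, atol=1e-12)
            np.testing.assert_allclose(f.N, first.N, atol=1e-12)
            np.testing.assert_allclose(f.B, first.B, atol=1e-12)

    def test_frames_orthonormal_right_handed(self, rng):
        t = np.linspace(0, 10, 300)
        pos = np.column_stack(
            [np.cos(t) + 0.3 * t, np.sin(1.3 * t), 0.2 * t**1.5]
        )
        fs = parallel_transport_frames(analytic_trajectory(t, pos))
        for f in fs.frames:
            assert f.is_valid(tol=1e-9)

    def test_planar_curve_constant_binormal(self):
        # N0 in the curve plane keeps B pinned to the plane normal
        t = np.linspace(0, 3 * np.pi, 800)
        pos = np.column_stack([np.cos(t) + 0.2 * t, np.sin(t), 0 * t])
        sm = analytic_trajectory(t, pos)
        T0 = tangent_vectors(sm)[0]
        in_plane = np.cross([0.0, 0, 1.0], T0)
        fs = parallel_transport_frames(sm, N0=in_plane)
        B = np.array([f.B for f in fs.frames])
        assert np.abs(B - B[0]).max() < 1e-6

    def test_closed_planar_loop_zero_holonomy(self):
        t = np.linspace(0, 2 * np.pi, 1500)
        pos = np.column_stack([np.cos(t), np.sin(t), 0 * t])
        fs = parallel_transport_frames(analytic_trajectory(t, pos))
        assert np.linalg.norm(fs.frames[-1].N - fs.frames[0].N) < 1e-3

    def test_minimal_twist_bound(self):
        # the normal never rotates about T by more than the tangent turn angle
        t = np.linspace(0, 8, 500)
        pos = np.column_stack([np.sin(t), t, 0.3 * np.cos(2 * t)])
        sm = analytic_trajectory(t, pos)
        fs = parallel_transport_frames(sm)
        T = np.array([f.T for f in fs.frames])
        N = np.array([f.N for f in fs.frames])
        for i in range(len(T) - 1):
            turn = np.arccos(np.clip(T[i] @ T[i + 1], -1, 1))
            n_angle = np.arccos(np.clip(N[i] @ N[i + 1], -1, 1))
            assert n_angle <= turn + 1e-9

    def test_refinement_stability(self):
        def frames_at(n):
            t = np.linspace(0, 10, n)
            pos = np.column_stack([np.cos(t), np.sin(t), 0.3 * t])
            return parallel_transport_frames(analytic_trajectory(t, pos))

        coarse = frames_at(2400).frames[-1].N
        fine = frames_at(4800).frames[-1].N
        assert np.linalg.norm(coarse - fine) < 1e-3


class TestReorient:
    def test_identity_frame_is_noop(self, icosahedron):
        frame = Frame(*np.eye(3), origin=np.zeros(3))
        out = reorient_mesh(icosahedron, frame)
        np.testing.assert_allclose(out.vertices, icosahedron.vertices, atol=1e-15)

    def test_isometry(self, icosahedron, rng):
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        T = u
        N = initial_normal(T)
        frame = Frame(T, N, np.cross(T, N), origin=rng.normal(size=3))
        out = reorient_mesh(icosahedron, frame)
        np.testing.assert_allclose(
            np.linalg.norm(out.vertices, axis=1),
            np.linalg.norm(icosahedron.vertices - frame.origin, axis=1),
            atol=1e-12,
        )

    def test_scene_rotation_cancels(self, icosahedron, rng):
        # rotating trajectory and mesh together leaves frame coordinates unchanged,
        # provided the initial normal is transported with the scene
        t = np.linspace(0, 5, 100)
        pos = np.column_stack([np.cos(t), np.sin(t), 0.4 * t])
        sm = analytic_trajectory(t, pos)
        fs = parallel_transport_frames(sm)
        frame = fs.frames[40]
        mesh = TriangleMesh(icosahedron.vertices + frame.origin, icosahedron.faces)
        base = reorient_mesh(mesh, frame)

        R = random_rotation(rng)
        sm_rot = analytic_trajectory(t, pos @ R.T)
        fs_rot = parallel_transport_frames(sm_rot, N0=R @ fs.frames[0].N)
        mesh_rot = TriangleMesh(mesh.vertices @ R.T, mesh.faces)
        rotated = reorient_mesh(mesh_rot, fs_rot.frames[40])
        np.testing.assert_allclose(rotated.vertices, base.vertices, atol=1e-6)


class TestIdentityFrames:
    def test_standard_basis_everywhere(self):
        t = np.arange(0.0, 6.0)
        sm = analytic_trajectory(t, np.column_stack([t, t**2, 0 * t]))
        fs = identity_frames(sm)
        for f in fs.frames:
            np.testing.assert_array_equal(f.matrix(), np.eye(3))
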