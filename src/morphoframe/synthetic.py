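"""Synthetic moving-cell dataset with known ground truth.

Emulates a motile near-spherical cell of unit volume moving along a
smooth 3D path with an accelerate-decelerate-accelerate-decelerate speed
profile (two Gaussian speed bumps over a small base speed) and one smooth
direction change in the slow phase between the bumps. While accelerating
the cell protrudes a pseudopod along its motion direction — protrusion
length scales linearly with instantaneous speed — and relaxes back to
near-spherical when decelerating. A small smooth radial perturbation
(low-order spherical-harmonic noise) stands in for surface texture.

The full time series has ``n_timepoints`` frames (default 250); meshes
are emitted only at the observed times t = 1, 10, 20, ..., 250 (26
observations by default), while the ground-truth trajectory, speed,
curvature, torsion, and protrusion direction are recorded at every frame,
mirroring an observed/holdout split.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import trimesh

from morphoframe.harmonics import real_sh
from morphoframe.mesh_io import TriangleMesh, mass_center, normalize_volume, write_mesh
from morphoframe.trajectory import SmoothTrajectory

logger = logging.getLogger(__name__)

#: radius of a unit-volume sphere
UNIT_VOLUME_RADIUS = (3.0 / (4.0 * np.pi)) ** (1.0 / 3.0)


def _default_observed_times() -> np.ndarray:
    return np.array([1] + list(range(10, 251, 10)))


@dataclass
class SyntheticCellConfig:
    """Study conditions for one synthetic cell.

    Speed is in cell-scale length units per frame; the two Gaussian bumps
    produce the accelerate-decelerate-accelerate-decelerate pattern, and
    the heading turns by ``turn_angle`` radians in a smooth window around
    ``turn_time`` (the slow phase between the bumps). ``pseudopod_amplitude``
    is the maximum protrusion length in cell radii, reached at peak speed.
    """

    n_timepoints: int = 250
    observed_times: np.ndarray = field(default_factory=_default_observed_times)
    # speed profile: base + two Gaussian bumps
    base_speed: float = 0.05
    bump_centers: tuple[float, float] = (65.0, 185.0)
    bump_widths: tuple[float, float] = (25.0, 25.0)
    bump_amplitudes: tuple[float, float] = (0.6, 0.6)
    # path: smooth in-plane turn plus a gentle pitch oscillation
    turn_angle: float = 1.2
    turn_time: float = 115.0
    turn_width: float = 10.0
    pitch_amplitude: float = 0.15
    # shape model
    pseudopod_amplitude: float = 0.6
    pseudopod_cap_sigma: float = 0.5
    noise_amplitude: float = 0.02
    subdivisions: int = 3
    deformation: str = "directional"  # or "isotropic"
    seed: int = 0

    def __post_init__(self):
        self.observed_times = np.asarray(self.observed_times, dtype=int)
        if self.observed_times.min() < 1 or self.observed_times.max() > self.n_timepoints:
            raise ValueError("observed_times must lie in 1..n_timepoints")
        if self.deformation not in ("directional", "isotropic"):
            raise ValueError("deformation must be 'directional' or 'isotropic'")

    @classmethod
    def scaled(cls, n_timepoints: int, observed_stride: int = 10, **overrides) -> "SyntheticCellConfig":
        """Default study conditions rescaled to a shorter movie.

        Keeps the default profile's proportions (bump centers at 26%/74%
        of the movie, turn in the slow phase between them) while changing
        only the movie length and observation stride.
        """
        f = n_timepoints / 250.0
        observed = sorted(
            set([1, n_timepoints]) | set(range(observed_stride, n_timepoints + 1, observed_stride))
        )
        params = dict(
            n_timepoints=n_timepoints,
            observed_times=np.array(observed),
            bump_centers=(65.0 * f, 185.0 * f),
            bump_widths=(25.0 * f, 25.0 * f),
            turn_time=115.0 * f,
            turn_width=10.0 * f,
        )
        params.update(overrides)
        return cls(**params)


@dataclass
class GroundTruth:
    """Per-frame truth for a generated cell."""

    times: np.ndarray
    trajectory: np.ndarray
    speed: np.ndarray
    curvature: np.ndarray
    torsion: np.ndarray
    protrusion_direction: np.ndarray


def speed_profile(times: np.ndarray, config: SyntheticCellConfig) -> np.ndarray:
    """Two-bump speed law (length units per frame)."""
    t = np.asarray(times, dtype=float)
    v = np.full_like(t, config.base_speed)
    for c, w, a in zip(config.bump_centers, config.bump_widths, config.bump_amplitudes):
        v = v + a * np.exp(-0.5 * ((t - c) / w) ** 2)
    return v


def _heading(times: np.ndarray, config: SyntheticCellConfig) -> np.ndarray:
    """Unit tangent directions of the path at the given times."""
    t = np.asarray(times, dtype=float)
    # smooth sigmoidal yaw turn; C-infinity
    yaw = config.turn_angle / (1.0 + np.exp(-(t - config.turn_time) / config.turn_width))
    pitch = config.pitch_amplitude * np.sin(2.0 * np.pi * t / config.n_timepoints)
    return np.column_stack(
        [np.cos(pitch) * np.cos(yaw), np.cos(pitch) * np.sin(yaw), np.sin(pitch)]
    )


def make_path(config: SyntheticCellConfig, fine_step: float = 0.1):
    """Integrate the speed/heading laws into a smooth 3D path.

    Returns ``(times, positions, fine_times, fine_positions)`` where
    ``times`` are the integer frames 1..n_timepoints and the fine grid is
    used for derivative-based ground truth.
    """
    tf = np.arange(1.0, config.n_timepoints + fine_step / 2, fine_step)
    vel = speed_profile(tf, config)[:, None] * _heading(tf, config)
    pos_f = np.vstack(
        [np.zeros(3), np.cumsum(0.5 * (vel[1:] + vel[:-1]) * fine_step, axis=0)]
    )
    times = np.arange(1, config.n_timepoints + 1)
    idx = np.round((times - 1) / fine_step).astype(int)
    return times, pos_f[idx], tf, pos_f


def ground_truth(config: SyntheticCellConfig) -> GroundTruth:
    """Exact trajectory and movement features at every frame."""
    from morphoframe.trajectory import movement_features

    times, pos, tf, pos_f = make_path(config)
    fine = SmoothTrajectory(tf, pos_f, np.zeros(3), np.ones(3), times.astype(float))
    feats = movement_features(fine)
    idx = np.round((times - 1) / (tf[1] - tf[0])).astype(int)
    return GroundTruth(
        times=times,
        trajectory=pos,
        speed=feats.speed[idx],
        curvature=feats.curvature[idx],
        torsion=feats.torsion[idx],
        protrusion_direction=_heading(times, config),
    )


def _sh_noise(theta, phi, rng: np.random.Generator, amplitude: float, l_noise: int = 4):
    """Smooth seeded radial perturbation from random low-order harmonics."""
    out = np.zeros_like(theta)
    for l in range(2, l_noise + 1):
        for m in range(-l, l + 1):
            out = out + rng.normal(0.0, 1.0) * real_sh(l, m, theta, phi)
    scale = np.max(np.abs(out)) or 1.0
    return amplitude * out / scale


def make_cell_mesh(
    center: np.ndarray,
    direction: np.ndarray,
    speed: float,
    config: SyntheticCellConfig,
    rng: np.random.Generator | None = None,
    time_index: int = 0,
) -> TriangleMesh:
    """Build one unit-volume cell mesh at the given position and state.

    Starts from a subdivided icosphere of unit-volume radius; vertices in
    an angular cap around ``direction`` are pushed outward by a smooth
    bump whose height follows the protrusion law
    ``pseudopod_amplitude * speed / max_speed`` (in cell radii). In
    ``isotropic`` mode the same deformation energy is spent on an
    orientation-free degree-2 breathing mode instead. Seeded low-order SH
    radial noise is added, and the mesh is rescaled to unit volume.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    base = trimesh.creation.icosphere(subdivisions=config.subdivisions, radius=1.0)
    v = np.asarray(base.vertices, float)
    unit = v / np.linalg.norm(v, axis=1, keepdims=True)
    theta = np.arccos(np.clip(unit[:, 2], -1, 1))
    phi = np.arctan2(unit[:, 1], unit[:, 0])

    vmax = speed_profile(np.arange(1, config.n_timepoints + 1), config).max()
    strength = config.pseudopod_amplitude * speed / vmax
    if config.deformation == "directional":
        ang = np.arccos(np.clip(unit @ direction, -1.0, 1.0))
        bump = strength * np.exp(-0.5 * (ang / config.pseudopod_cap_sigma) ** 2)
    else:
        # orientation-free: axisymmetric degree-2 breathing about z
        bump = strength * 0.5 * (3.0 * unit[:, 2] ** 2 - 1.0) / 2.0
    radial = 1.0 + bump + _sh_noise(theta, phi, rng, config.noise_amplitude)
    verts = unit * (UNIT_VOLUME_RADIUS * radial)[:, None]
    mesh = TriangleMesh(verts, np.asarray(base.faces), time_index=time_index)
    mesh = normalize_volume(mesh)
    mesh.vertices = mesh.vertices - mass_center(mesh) + np.asarray(center, float)
    return mesh


def generate_dataset(
    config: SyntheticCellConfig, out_dir: str | Path | None = None, cell_id: str = "cell"
) -> tuple[list[TriangleMesh], GroundTruth]:
    """Generate the observed mesh series and full ground truth.

    Meshes are produced at ``config.observed_times`` only; ground truth
    covers every frame. With ``out_dir`` set, writes OBJ meshes, a
    manifest CSV (cell_id, time_index, path), and a ground-truth CSV.
    Deterministic per seed.
    """
    rng = np.random.default_rng(config.seed)
    truth = ground_truth(config)
    meshes = []
    for t in config.observed_times:
        i = int(t) - 1
        meshes.append(
            make_cell_mesh(
                truth.trajectory[i],
                truth.protrusion_direction[i],
                truth.speed[i],
                config,
                rng=rng,
                time_index=int(t),
            )
        )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "manifest.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["cell_id", "time_index", "path"])
            for mesh in meshes:
                name = f"{cell_id}_t{mesh.time_index}.obj"
                write_mesh(mesh, out_dir / name)
                w.writerow([cell_id, mesh.time_index, name])
        with open(out_dir / "ground_truth.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["t", "x", "y", "z", "speed", "curvature", "torsion"])
            for i, t in enumerate(truth.times):
                w.writerow(
                    [t, *truth.trajectory[i], truth.speed[i], truth.curvature[i], truth.torsion[i]]
                )
    return meshes, truth


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (quaternion method)."""
    q = rng.normal(size=4)
    q = q / np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def generate_cohort(
    n_per_group: int,
    base_config: SyntheticCellConfig,
    seed: int = 0,
) -> tuple[dict[str, list[TriangleMesh]], dict[str, str]]:
    """Two-group cohort: directional vs isotropic deformation.

    Each cell gets an independent noise seed and an independent random
    rigid rotation of its whole scene (meshes and path together), so that
    shape deformation has a consistent relation to the motion direction
    only in the ``directional`` group and world-frame coordinates carry
    no preferred axis. Returns ``(cells, labels)`` keyed by cell id.
    """
    rng = np.random.default_rng(seed)
    cells: dict[str, list[TriangleMesh]] = {}
    labels: dict[str, str] = {}
    for mode in ("directional", "isotropic"):
        for i in range(n_per_group):
            cid = f"{mode[:3]}_{i:02d}"
            cfg = replace(base_config, deformation=mode, seed=int(rng.integers(2**31 - 1)))
            meshes, _ = generate_dataset(cfg)
            R = _random_rotation(rng)
            for m in meshes:
                m.vertices = m.vertices @ R.T
            cells[cid] = meshes
            labels[cid] = mode
    return cells, labels


def evaluate_trajectory_mse(smooth: SmoothTrajectory, truth: GroundTruth) -> dict:
    """Mean squared reconstruction error of the smooth trajectory.

    Reports two averaging conventions: ``per_point`` averages the squared
    Euclidean distance over the ground-truth frames, ``per_coordinate``
    averages squared scalar residuals over all frames x 3 coordinates
    (one third of per_point). The smooth curve is linearly interpolated
    from its dense grid onto the truth frames.
    """
    t = truth.times.astype(float)
    if t.min() < smooth.times.min() - 1e-9 or t.max() > smooth.times.max() + 1e-9:
        raise ValueError("ground-truth times extend beyond the smooth trajectory")
    interp = np.column_stack(
        [np.interp(t, smooth.times, smooth.points[:, k]) for k in range(3)]
    )
    sq = np.sum((interp - truth.trajectory) ** 2, axis=1)
    return {"per_point": float(sq.mean()), "per_coordinate": float(sq.mean() / 3.0)}
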