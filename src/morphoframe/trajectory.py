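"""Gaussian-process trajectory smoothing and differential movement features.

Each coordinate of the mass-center sequence is modeled as s(t) = f(t) + eps,
with f a zero-mean Gaussian process under a squared-exponential kernel and
eps i.i.d. Gaussian observation noise. The sequence is standardized to mean
zero / unit standard deviation before fitting and destandardized after
posterior-mean interpolation on a dense grid. Speed, curvature, and torsion
are read off the dense smooth curve by finite differences:

    speed = |r'|,  kappa = |r' x r''| / |r'|^3,
    tau = (r' x r'') . r''' / |r' x r''|^2.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

from morphoframe.errors import DegenerateAxisError

logger = logging.getLogger(__name__)


@dataclass
class RawTrajectory:
    """Observed mass-center positions at (strictly increasing) times."""

    times: np.ndarray
    positions: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (len(self.times), 3):
            raise ValueError("positions must be (n_times, 3)")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class GPConfig:
    """Kernel and interpolation settings for trajectory smoothing.

    ``kernel_length_scale`` and ``kernel_variance`` parameterize the
    squared-exponential kernel k(t,t') = v * exp(-(t-t')^2 / (2 l^2));
    defaults are l = e^1 and v = 1 on the standardized scale.
    ``noise_variance`` is the observation-noise variance sigma^2;
    ``"optimize"`` maximizes the marginal likelihood over sigma^2 with
    (l, v) held fixed. ``interpolation_factor`` is the number of dense
    subdivisions per original interval (1 = no new points).
    ``time_scale`` sets the axis on which the kernel measures distance:
    ``"index"`` (default) numbers the observations 1..n so that l = e
    spans about three observations regardless of the sampling stride;
    ``"raw"`` uses the time stamps as given.
    """

    kernel_length_scale: float = math.e
    kernel_variance: float = 1.0
    noise_variance: float | str = "optimize"
    interpolation_factor: int = 10
    time_scale: str = "index"  # kernel distance: observation rank or raw time

    def __post_init__(self):
        if self.kernel_length_scale <= 0 or self.kernel_variance <= 0:
            raise ValueError("kernel parameters must be positive")
        if not (self.noise_variance == "optimize" or float(self.noise_variance) > 0):
            raise ValueError("noise_variance must be positive or 'optimize'")
        if int(self.interpolation_factor) < 1:
            raise ValueError("interpolation_factor must be >= 1")
        self.interpolation_factor = int(self.interpolation_factor)
        if self.time_scale not in ("index", "raw"):
            raise ValueError("time_scale must be 'index' or 'raw'")


@dataclass
class SmoothTrajectory:
    """Dense GP posterior-mean curve r(t) with standardization constants."""

    times: np.ndarray
    points: np.ndarray
    means: np.ndarray  # per-axis standardization mean
    sds: np.ndarray  # per-axis standardization sd
    original_times: np.ndarray

    def index_of_time(self, t: float) -> int:
        """Dense-grid index of an (original) time stamp."""
        idx = int(np.argmin(np.abs(self.times - t)))
        if abs(self.times[idx] - t) > 1e-9 * max(1.0, abs(t)):
            raise KeyError(f"time {t} not on the dense grid")
        return idx


@dataclass
class MovementFeatures:
    """Per-dense-sample speed, curvature, and torsion.

    Curvature and torsion are NaN where the speed (or the curvature, for
    torsion) falls below the degeneracy threshold.
    """

    times: np.ndarray
    speed: np.ndarray
    curvature: np.ndarray
    torsion: np.ndarray


def standardize_sequence(values) -> tuple[np.ndarray, float, float]:
    """Shift/scale a sequence to mean 0 and (population) sd 1.

    Returns ``(standardized, mean, sd)``; a zero-variance sequence raises
    :class:`~morphoframe.errors.DegenerateAxisError` so the caller can
    treat the axis as constant and skip the GP fit for it.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("need at least 2 values")
    mean = float(v.mean())
    sd = float(v.std())  # population convention
    if sd == 0.0:
        raise DegenerateAxisError("zero-variance coordinate sequence")
    return (v - mean) / sd, mean, sd


def destandardize_sequence(values, mean: float, sd: float) -> np.ndarray:
    """Invert :func:`standardize_sequence`: multiply by sd, add mean."""
    return np.asarray(values, dtype=float) * sd + mean


def fit_gp(times, values, config: GPConfig) -> GaussianProcessRegressor:
    """Fit a zero-mean GP with SE kernel to one standardized coordinate.

    Returns the fitted regressor; its posterior mean is evaluable at any
    time via ``.predict``. When ``config.noise_variance == "optimize"`` the
    white-noise variance alone is tuned by marginal-likelihood
    maximization; the SE length scale and variance stay fixed.
    """
    t = np.asarray(times, dtype=float).reshape(-1, 1)
    y = np.asarray(values, dtype=float)
    if len(np.unique(t)) != len(t):
        raise ValueError("times must be distinct")
    se = ConstantKernel(config.kernel_variance, "fixed") * RBF(
        config.kernel_length_scale, "fixed"
    )
    if config.noise_variance == "optimize":
        kernel = se + WhiteKernel(1e-2, (1e-10, 1e2))
        gp = GaussianProcessRegressor(
            kernel=kernel, normalize_y=False, n_restarts_optimizer=2, random_state=0
        )
    else:
        kernel = se + WhiteKernel(float(config.noise_variance), "fixed")
        gp = GaussianProcessRegressor(kernel=kernel, normalize_y=False, optimizer=None)
    gp.fit(t, y)
    return gp


def dense_grid(times: np.ndarray, factor: int) -> np.ndarray:
    """Original times plus ``factor - 1`` equally spaced points per interval."""
    times = np.asarray(times, dtype=float)
    if factor == 1:
        return times.copy()
    pieces = []
    for a, b in zip(times[:-1], times[1:]):
        pieces.append(np.linspace(a, b, factor + 1)[:-1])
    pieces.append(times[-1:])
    return np.concatenate(pieces)


def smooth_trajectory(raw: RawTrajectory, config: GPConfig | None = None) -> SmoothTrajectory:
    """Standardize, GP-fit, and densely interpolate a mass-center sequence.

    Each coordinate axis is processed independently (standardize ->
    zero-mean GP with SE kernel -> posterior mean on the dense grid ->
    destandardize). A constant axis bypasses the GP and is carried through
    unchanged.
    """
    config = config or GPConfig()
    if config.time_scale == "index":
        axis = np.arange(1.0, len(raw.times) + 1.0)
    else:
        axis = raw.times
    grid_axis = dense_grid(axis, config.interpolation_factor)
    # dense times map linearly within each original interval
    grid = np.interp(grid_axis, axis, raw.times)
    points = np.empty((len(grid), 3))
    means = np.empty(3)
    sds = np.empty(3)
    for ax in range(3):
        coord = raw.positions[:, ax]
        try:
            z, mean, sd = standardize_sequence(coord)
        except DegenerateAxisError:
            logger.info("axis %d is constant; skipping GP", ax)
            points[:, ax] = coord[0]
            means[ax], sds[ax] = coord[0], 1.0
            continue
        gp = fit_gp(axis, z, config)
        points[:, ax] = destandardize_sequence(gp.predict(grid_axis.reshape(-1, 1)), mean, sd)
        means[ax], sds[ax] = mean, sd
    return SmoothTrajectory(grid, points, means, sds, raw.times.copy())


def _finite_difference(points: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Central differences on a (possibly non-uniform) grid, one-sided at ends."""
    return np.gradient(points, times, axis=0)


def movement_features(
    smooth: SmoothTrajectory,
    speed_threshold: float = 1e-12,
    torsion_threshold: float = 1e-8,
) -> MovementFeatures:
    """Speed, curvature, and torsion of the dense smooth curve.

    Derivatives use central finite differences on the dense grid.
    Where |r'| < ``speed_threshold`` the speed is set to 0 and curvature
    and torsion are NaN; where |r' x r''| < ``torsion_threshold`` * |r'|^3
    (near-zero curvature) the torsion is NaN.
    """
    if len(smooth.times) < 5:
        raise ValueError("need at least 5 dense points for stable derivatives")
    t = smooth.times
    d1 = _finite_difference(smooth.points, t)
    d2 = _finite_difference(d1, t)
    d3 = _finite_difference(d2, t)
    speed = np.linalg.norm(d1, axis=1)
    cross = np.cross(d1, d2)
    cross_norm = np.linalg.norm(cross, axis=1)

    curvature = np.full_like(speed, np.nan)
    torsion = np.full_like(speed, np.nan)
    moving = speed > speed_threshold
    curvature[moving] = cross_norm[moving] / speed[moving] ** 3
    valid_tau = moving & (cross_norm > torsion_threshold * speed**3)
    torsion[valid_tau] = (
        np.einsum("ij,ij->i", cross[valid_tau], d3[valid_tau]) / cross_norm[valid_tau] ** 2
    )
    speed = np.where(moving, speed, 0.0)
    return MovementFeatures(t.copy(), speed, curvature, torsion)
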