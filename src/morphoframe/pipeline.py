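"""End-to-end orchestration: mesh time series in, features and reports out.

``run_cell`` executes the full chain for one cell — mass centers ->
GP-smoothed trajectory -> parallel-transport frames -> mesh reorientation
-> volume normalization -> mean-curvature-flow spherical parameterization
-> spherical-harmonic fit -> eccentricities and shape-change rate ->
movement features -> 26-feature aggregation. ``run_cohort`` maps it over
labelled cells and runs the statistical battery, including the
standard-basis ablation (identity frames, i.e. no realignment) against
which the moving-frame features are compared.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from morphoframe import features_stats
from morphoframe.errors import MorphoframeError
from morphoframe.harmonics import (
    SHBasis,
    eccentricities,
    fit_coefficients,
    shape_change_rate,
)
from morphoframe.mesh_io import TriangleMesh, check_spherical_topology, mass_center, normalize_volume
from morphoframe.moving_frame import identity_frames, parallel_transport_frames, reorient_mesh
from morphoframe.spherical_param import mcf_spherical_parameterization
from morphoframe.trajectory import GPConfig, RawTrajectory, movement_features, smooth_trajectory

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Knobs for one pipeline run."""

    gp: GPConfig = field(default_factory=GPConfig)
    l_max: int = 6
    mcf_max_iters: int = 500
    mcf_tol: float = 0.01
    standard_basis: bool = False  # ablation: skip realignment
    min_timepoints: int = 6
    seed: int = 0


@dataclass
class CellResult:
    """Per-time measures and the aggregated feature row for one cell."""

    cell_id: str
    per_time: pd.DataFrame
    features: features_stats.CellFeatures


def run_cell(
    meshes: list[TriangleMesh], config: RunConfig | None = None, cell_id: str = "cell",
    group: str | None = None,
) -> CellResult:
    """Full shape-movement analysis of one cell's mesh time series."""
    config = config or RunConfig()
    meshes = sorted(meshes, key=lambda m: m.time_index)
    valid = []
    for m in meshes:
        if check_spherical_topology(m):
            valid.append(m)
        else:
            logger.warning("cell %s t=%d: not closed genus-0; excluded", cell_id, m.time_index)
    if len(valid) < config.min_timepoints:
        raise MorphoframeError(
            f"cell {cell_id!r}: only {len(valid)} usable time points "
            f"(< {config.min_timepoints}); cell excluded"
        )
    times = np.array([m.time_index for m in valid], dtype=float)
    centers = np.array([mass_center(m) for m in valid])
    smooth = smooth_trajectory(RawTrajectory(times, centers), config.gp)
    frames = (
        identity_frames(smooth) if config.standard_basis else parallel_transport_frames(smooth)
    )
    feats = movement_features(smooth)

    basis = SHBasis(config.l_max)
    coeffs, exy, exz = [], [], []
    for m in valid:
        frame = frames.at_time(m.time_index)
        reoriented = reorient_mesh(m, frame)
        normed = normalize_volume(reoriented)
        smap = mcf_spherical_parameterization(
            normed, max_iters=config.mcf_max_iters, tol=config.mcf_tol
        )
        c = fit_coefficients(smap, basis)
        ecc = eccentricities(c)
        coeffs.append(c)
        exy.append(ecc.E_xy)
        exz.append(ecc.E_xz)
    rates = shape_change_rate(coeffs)

    obs_idx = np.array([smooth.index_of_time(t) for t in times])
    per_time = pd.DataFrame(
        {
            "t": times,
            "x": centers[:, 0],
            "y": centers[:, 1],
            "z": centers[:, 2],
            "speed": feats.speed[obs_idx],
            "curvature": feats.curvature[obs_idx],
            "torsion": feats.torsion[obs_idx],
            "E_xy": exy,
            "E_xz": exz,
            "shape_change_rate": np.append(rates, np.nan),
        }
    )
    cell_features = features_stats.aggregate_features(
        speed=per_time["speed"],
        curvature=per_time["curvature"],
        torsion=per_time["torsion"],
        shape_change_rate=rates,
        E_xy=exy,
        E_xz=exz,
        cell_id=cell_id,
        group=group,
        min_timepoints=config.min_timepoints,
    )
    return CellResult(cell_id, per_time, cell_features)


def run_cohort(
    cells: dict[str, list[TriangleMesh]],
    labels: dict[str, str] | None = None,
    config: RunConfig | None = None,
    compare_standard_basis: bool = True,
) -> dict:
    """Analyze a labelled cohort and run the statistical battery.

    Returns a report dict with the moving-frame feature table, the
    standard-basis ablation table, the Kendall matrix, a UMAP embedding
    (when enough cells), per-k KNN cross-validation accuracies for both
    bases with paired t-tests, and permutation importances. Cells that
    fail (too few usable meshes, degenerate stages) are skipped and
    listed under ``excluded``.
    """
    config = config or RunConfig()
    labels = labels or {}
    report: dict = {"seed": config.seed, "excluded": {}}

    def _table(standard: bool) -> pd.DataFrame:
        cfg = RunConfig(**{**config.__dict__, "standard_basis": standard})
        rows = []
        for cid, meshes in cells.items():
            try:
                rows.append(run_cell(meshes, cfg, cell_id=cid, group=labels.get(cid)).features)
            except MorphoframeError as exc:
                report["excluded"][cid] = str(exc)
                logger.warning("cohort: %s", exc)
        return features_stats.features_to_table(rows)

    mf = _table(standard=False)
    report["features_moving_frame"] = mf
    std_mf, consts = features_stats.standardize_table(mf)
    report["standardization_constants"] = consts
    report["kendall"] = features_stats.kendall_matrix(std_mf)
    if len(std_mf) >= 20:
        report["embedding"] = features_stats.embed_2d(std_mf, seed=config.seed)
    else:
        logger.info("cohort too small for the default UMAP neighborhood; embedding skipped")

    y = mf.get("group")
    if y is not None and y.notna().all() and y.nunique() >= 2:
        acc_mf = features_stats.knn_cv(std_mf, y, seed=config.seed)
        report["knn_moving_frame"] = acc_mf
        if compare_standard_basis:
            sb = _table(standard=True)
            report["features_standard_basis"] = sb
            std_sb, _ = features_stats.standardize_table(sb)
            acc_sb = features_stats.knn_cv(std_sb, sb["group"], seed=config.seed)
            report["knn_standard_basis"] = acc_sb
            report["ttests"] = {
                k: features_stats.paired_accuracy_ttest(acc_mf[k], acc_sb[k]) for k in acc_mf
            }
        from sklearn.neighbors import KNeighborsClassifier

        X = std_mf[[c for c in std_mf.columns if c != "group"]].to_numpy(float)
        knn = KNeighborsClassifier(n_neighbors=5).fit(X, y)
        report["permutation_importance"] = features_stats.permutation_importance(
            std_mf, y, knn, seed=config.seed
        )
    else:
        logger.info("no usable labels; classification battery skipped")
    return report
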