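"""Per-cell feature aggregation and the statistical battery.

Six per-time-point quantities — speed, curvature, torsion, shape-change
rate, E_xy, E_xz — are each summarized by median, median absolute
deviation (raw, no consistency factor), 25th percentile, and 75th
percentile; adding the peak counts of the curvature and torsion series
gives exactly 26 features per cell. E_yz is excluded as redundant
(E_yz = E_xz / E_xy). Downstream: column z-scoring, Kendall tau-b
correlation, seeded UMAP embedding, stratified 10-fold KNN
cross-validation over k in {3, 5, 10, 15, 20, 25}, a one-sample t-test on
paired per-fold accuracy differences, and permutation feature importance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.inspection import permutation_importance as _sk_permutation_importance
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier

logger = logging.getLogger(__name__)

QUANTITIES = ("speed", "curvature", "torsion", "shape_change_rate", "E_xy", "E_xz")
STATS = ("median", "mad", "p25", "p75")

#: canonical 26 feature names, fixed column order
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{q}_{s}" for q in QUANTITIES for s in STATS
) + ("n_peaks_curvature", "n_peaks_torsion")

DEFAULT_KNN_KS = (3, 5, 10, 15, 20, 25)


@dataclass
class CellFeatures:
    """The 26-value shape-movement summary of one cell."""

    cell_id: str
    values: dict[str, float]
    group: str | None = None

    def __post_init__(self):
        if set(self.values) != set(FEATURE_NAMES):
            raise ValueError("feature dict must contain exactly the 26 canonical features")

    def as_series(self) -> pd.Series:
        return pd.Series({k: self.values[k] for k in FEATURE_NAMES}, name=self.cell_id)


def count_peaks(series, prominence: float = 0.0) -> int:
    """Number of interior local maxima of a series.

    Runs of equal values collapse to a single sample first, so a plateau
    counts as one peak. Maxima must be strict after collapsing and exceed
    ``prominence`` over the higher of their two flanking minima. Missing
    values are dropped with a warning.
    """
    v = np.asarray(series, dtype=float)
    if np.isnan(v).any():
        warnings.warn("dropping missing values before peak counting")
        v = v[~np.isnan(v)]
    if len(v) < 3:
        return 0
    # collapse equal runs
    keep = np.concatenate([[True], np.diff(v) != 0])
    v = v[keep]
    if len(v) < 3:
        return 0
    peaks = 0
    for i in range(1, len(v) - 1):
        if v[i] > v[i - 1] and v[i] > v[i + 1]:
            if prominence > 0:
                left_min = v[:i].min()
                right_min = v[i + 1 :].min()
                if v[i] - max(left_min, right_min) < prominence:
                    continue
            peaks += 1
    return peaks


def aggregate_features(
    speed,
    curvature,
    torsion,
    shape_change_rate,
    E_xy,
    E_xz,
    cell_id: str = "cell",
    group: str | None = None,
    min_timepoints: int = 6,
) -> CellFeatures:
    """Collapse one cell's per-time measures into the 26 features.

    Requires at least ``min_timepoints`` observations (cells with fewer
    are excluded upstream). NaNs within a series (e.g. undefined torsion)
    are ignored by the order statistics.
    """
    series = {
        "speed": np.asarray(speed, float),
        "curvature": np.asarray(curvature, float),
        "torsion": np.asarray(torsion, float),
        "shape_change_rate": np.asarray(shape_change_rate, float),
        "E_xy": np.asarray(E_xy, float),
        "E_xz": np.asarray(E_xz, float),
    }
    if len(series["speed"]) < min_timepoints:
        raise ValueError(
            f"cell {cell_id!r} has {len(series['speed'])} time points; need >= {min_timepoints}"
        )
    values: dict[str, float] = {}
    for name, v in series.items():
        clean = v[~np.isnan(v)]
        if clean.size == 0:
            clean = np.array([0.0])
            logger.warning("cell %s: quantity %s all-missing; using 0", cell_id, name)
        med = float(np.median(clean))
        values[f"{name}_median"] = med
        values[f"{name}_mad"] = float(np.median(np.abs(clean - med)))
        values[f"{name}_p25"] = float(np.percentile(clean, 25))
        values[f"{name}_p75"] = float(np.percentile(clean, 75))
    values["n_peaks_curvature"] = float(count_peaks(series["curvature"]))
    values["n_peaks_torsion"] = float(count_peaks(series["torsion"]))
    return CellFeatures(cell_id, values, group)


def features_to_table(cells: list[CellFeatures]) -> pd.DataFrame:
    """Stack per-cell features into a DataFrame (rows = cells).

    A ``group`` column is appended when any cell carries a label.
    """
    df = pd.DataFrame([c.as_series() for c in cells])
    groups = [c.group for c in cells]
    if any(g is not None for g in groups):
        df["group"] = groups
    return df


def _feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c != "group"]


def standardize_table(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Column-wise z-scores; returns (standardized table, constants).

    Constant columns are dropped with a warning; a single-row table is an
    error. The constants frame holds each column's (mean, sd) for
    inversion.
    """
    if len(table) < 2:
        raise ValueError("need at least 2 rows to standardize")
    out = table.copy()
    stats_rows = {}
    for col in _feature_columns(table):
        x = table[col].to_numpy(dtype=float)
        mean, sd = float(x.mean()), float(x.std())
        if sd == 0.0:
            warnings.warn(f"dropping constant feature column {col!r}")
            out = out.drop(columns=[col])
            continue
        out[col] = (x - mean) / sd
        stats_rows[col] = {"mean": mean, "sd": sd}
    return out, pd.DataFrame(stats_rows).T


def kendall_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Kendall tau-b rank-correlation matrix of the feature columns."""
    if len(table) < 3:
        raise ValueError("need at least 3 rows")
    return table[_feature_columns(table)].corr(method="kendall")


def embed_2d(
    table: pd.DataFrame,
    n_neighbors: int = 20,
    min_dist: float = 0.1,
    metric: str = "euclidean",
    seed: int = 0,
) -> np.ndarray:
    """Seeded 2-component UMAP embedding of the feature rows."""
    import umap  # deferred: heavy import

    X = table[_feature_columns(table)].to_numpy(dtype=float)
    if len(X) < n_neighbors:
        raise ValueError(f"need at least n_neighbors={n_neighbors} rows (got {len(X)})")
    reducer = umap.UMAP(
        n_neighbors=n_neighbors,
        n_components=2,
        min_dist=min_dist,
        metric=metric,
        random_state=seed,
    )
    return np.asarray(reducer.fit_transform(X))


def knn_cv(
    table: pd.DataFrame,
    labels,
    ks=DEFAULT_KNN_KS,
    folds: int = 10,
    seed: int = 0,
) -> dict[int, np.ndarray]:
    """Stratified k-fold KNN accuracy per neighborhood size.

    Returns ``{k: per-fold accuracy array}``. Folds are stratified and
    seeded, so runs with the same seed reuse identical partitions — which
    is what makes accuracies comparable across feature sets.
    """
    X = table[_feature_columns(table)].to_numpy(dtype=float)
    y = np.asarray(labels)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ValueError(
            f"smallest class has {counts.min()} members; need >= {folds} for stratification"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    out: dict[int, np.ndarray] = {}
    for k in ks:
        accs = []
        for train, test in splits:
            clf = KNeighborsClassifier(n_neighbors=min(k, len(train)))
            clf.fit(X[train], y[train])
            accs.append(float(np.mean(clf.predict(X[test]) == y[test])))
        out[k] = np.array(accs)
    return out


def paired_accuracy_ttest(acc_a, acc_b) -> tuple[float, float]:
    """One-sample t-test of per-fold accuracy differences against zero.

    Returns (mean difference a - b, two-sided p-value); a degenerate
    zero-variance difference vector yields p = NaN with a warning.
    """
    a = np.asarray(acc_a, float)
    b = np.asarray(acc_b, float)
    if a.shape != b.shape or len(a) < 2:
        raise ValueError("need two equal-length vectors of >= 2 accuracies")
    d = a - b
    if np.allclose(d.std(), 0.0) and not np.allclose(d.mean(), 0.0):
        warnings.warn("zero-variance nonzero differences; p-value undefined")
        return float(d.mean()), float("nan")
    t = stats.ttest_1samp(d, 0.0)
    return float(d.mean()), float(t.pvalue)


def permutation_importance(
    table: pd.DataFrame, labels, fitted_knn, n_repeats: int = 10, seed: int = 0
) -> pd.Series:
    """Mean accuracy drop when each feature column is shuffled."""
    cols = _feature_columns(table)
    X = table[cols].to_numpy(dtype=float)
    res = _sk_permutation_importance(
        fitted_knn, X, np.asarray(labels), n_repeats=n_repeats, random_state=seed,
        scoring="accuracy",
    )
    return pd.Series(res.importances_mean, index=cols)
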