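import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from sklearn.neighbors import KNeighborsClassifier

from morphoframe.features_stats import (
    FEATURE_NAMES,
    aggregate_features,
    count_peaks,
    embed_2d,
    features_to_table,
    kendall_matrix,
    knn_cv,
    paired_accuracy_ttest,
    permutation_importance,
    standardize_table,
)


def random_features_table(rng, n_rows, shift=0.0):
    data = rng.normal(shift, 1.0, size=(n_rows, 26))
    return pd.DataFrame(data, columns=list(FEATURE_NAMES))


class TestCountPeaks:
    @pytest.mark.parametrize(
        "series,expected",
        [
            ([0, 1, 0, 1, 0], 2),
            ([0, 1, 2, 3, 4], 0),
            ([4, 3, 2, 1], 0),
            ([0, 1, 1, 0], 1),  # plateau collapses to one peak
            ([0, 2, 0, 2, 0, 2, 0], 3),
            ([1, 1, 1, 1], 0),
        ],
    )
    def test_cases(self, series, expected):
        assert count_peaks(series) == expected

    def test_missing_values_dropped(self):
        with pytest.warns(UserWarning):
            n = count_peaks([0.0, np.nan, 1.0, 0.0, np.nan])
        assert n == 1

    def test_prominence_filter(self):
        series = [0, 0.05, 0, 1.0, 0]
        assert count_peaks(series) == 2
        assert count_peaks(series, prominence=0.5) == 1


class TestAggregate:
    def _measures(self, rng, n=10):
        return {
            "speed": rng.uniform(0, 2, n),
            "curvature": rng.uniform(0, 1, n),
            "torsion": rng.normal(0, 1, n),
            "shape_change_rate": rng.uniform(0, 0.5, n - 1),
            "E_xy": rng.uniform(0.8, 2.0, n),
            "E_xz": rng.uniform(0.8, 2.0, n),
        }

    def test_exactly_26_features(self, rng):
        cf = aggregate_features(cell_id="c1", **self._measures(rng))
        assert len(cf.values) == 26
        assert set(cf.values) == set(FEATURE_NAMES)

    def test_constant_speed_statistics(self, rng):
        m = self._measures(rng)
        m["speed"] = np.full(10, 1.7)
        cf = aggregate_features(cell_id="c", **m)
        assert cf.values["speed_median"] == 1.7
        assert cf.values["speed_p25"] == 1.7
        assert cf.values["speed_p75"] == 1.7
        assert cf.values["speed_mad"] == 0.0

    def test_percentiles_match_sort_oracle(self, rng):
        m = self._measures(rng, n=41)
        cf = aggregate_features(cell_id="c", **m)
        v = np.sort(m["E_xy"])
        # linear interpolation between order statistics at p=0.25: index 10 of 0..40
        assert cf.values["E_xy_p25"] == pytest.approx(v[10])
        assert cf.values["E_xy_median"] == pytest.approx(v[20])
        assert cf.values["E_xy_p75"] == pytest.approx(v[30])
        med = np.median(m["torsion"])
        assert cf.values["torsion_mad"] == pytest.approx(
            np.median(np.abs(m["torsion"] - med))
        )

    def test_too_few_timepoints_excluded(self, rng):
        m = {k: v[:5] for k, v in self._measures(rng).items()}
        with pytest.raises(ValueError):
            aggregate_features(cell_id="short", **m)

    def test_order_is_canonical(self, rng):
        cf = aggregate_features(cell_id="c", **self._measures(rng))
        assert list(cf.as_series().index) == list(FEATURE_NAMES)


class TestStandardize:
    def test_zero_mean_unit_sd(self, rng):
        table = random_features_table(rng, 15, shift=3.0)
        std, consts = standardize_table(table)
        np.testing.assert_allclose(std.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(std.std(axis=0, ddof=0), 1.0, atol=1e-9)
        assert set(consts.columns) == {"mean", "sd"}

    def test_round_trip(self, rng):
        table = random_features_table(rng, 8)
        std, consts = standardize_table(table)
        back = std * consts["sd"] + consts["mean"]
        np.testing.assert_allclose(back.to_numpy(), table.to_numpy(), atol=1e-12)

    def test_hand_zscore_toy(self):
        table = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [2.0, 4.0, 6.0]})
        std, _ = standardize_table(table)
        r = np.sqrt(3.0 / 2.0)
        np.testing.assert_allclose(std["a"], [-r, 0.0, r])
        np.testing.assert_allclose(std["b"], [-r, 0.0, r])

    def test_constant_column_dropped(self, rng):
        table = random_features_table(rng, 6)
        table["speed_mad"] = 1.0
        with pytest.warns(UserWarning):
            std, _ = standardize_table(table)
        assert "speed_mad" not in std.columns

    def test_single_row_rejected(self, rng):
        with pytest.raises(ValueError):
            standardize_table(random_features_table(rng, 1))


class TestKendall:
    def test_identical_and_reversed_columns(self):
        x = np.arange(10.0)
        table = pd.DataFrame({"a": x, "b": x, "c": -x})
        tau = kendall_matrix(table)
        assert tau.loc["a", "b"] == pytest.approx(1.0)
        assert tau.loc["a", "c"] == pytest.approx(-1.0)
        np.testing.assert_allclose(np.diag(tau), 1.0)

    def test_matches_pair_counting_oracle(self, rng):
        a = rng.normal(size=5)
        b = rng.normal(size=5)
        tau = kendall_matrix(pd.DataFrame({"a": a, "b": b})).loc["a", "b"]
        concordant = discordant = 0
        for i in range(5):
            for j in range(i + 1, 5):
                s = np.sign((a[i] - a[j]) * (b[i] - b[j]))
                concordant += s > 0
                discordant += s < 0
        assert tau == pytest.approx((concordant - discordant) / 10.0)


class TestEmbedding:
    def test_shape_determinism_and_separation(self, rng):
        # two well-separated feature blobs must stay separated in 2D
        a = random_features_table(rng, 15, shift=0.0)
        b = random_features_table(rng, 15, shift=8.0)
        table = pd.concat([a, b], ignore_index=True)
        emb1 = embed_2d(table, seed=3)
        emb2 = embed_2d(table, seed=3)
        assert emb1.shape == (30, 2)
        np.testing.assert_allclose(emb1, emb2)
        from sklearn.metrics import silhouette_score

        labels = np.repeat([0, 1], 15)
        assert silhouette_score(emb1, labels) > 0.5

    def test_too_few_rows(self, rng):
        with pytest.raises(ValueError):
            embed_2d(random_features_table(rng, 5))


class TestKnnCV:
    def test_separable_classes_perfect_accuracy(self, rng):
        a = random_features_table(rng, 20, shift=0.0)
        b = random_features_table(rng, 20, shift=30.0)
        table = pd.concat([a, b], ignore_index=True)
        labels = np.repeat(["lo", "hi"], 20)
        accs = knn_cv(table, labels, ks=(3, 5), folds=10, seed=0)
        for k, acc in accs.items():
            assert len(acc) == 10
            np.testing.assert_allclose(acc, 1.0)

    def test_random_labels_near_chance(self, rng):
        table = random_features_table(rng, 60)
        means = []
        for seed in range(5):
            labels = np.random.default_rng(seed).permutation(np.repeat(["a", "b"], 30))
            accs = knn_cv(table, labels, ks=(5,), folds=10, seed=seed)
            means.append(accs[5].mean())
        assert abs(np.mean(means) - 0.5) < 0.1

    def test_stratification_contract(self, rng):
        from sklearn.model_selection import StratifiedKFold

        y = np.repeat(["a", "b"], 25)
        skf = StratifiedKFold(n_splits=10, shuffle=True, random_state=0)
        for _, test in skf.split(np.zeros((50, 1)), y):
            assert len(test) == 5
            _, counts = np.unique(y[test], return_counts=True)
            assert np.abs(counts - 2.5).max() <= 0.5

    def test_small_class_rejected(self, rng):
        table = random_features_table(rng, 12)
        labels = ["a"] * 9 + ["b"] * 3
        with pytest.raises(ValueError):
            knn_cv(table, labels, folds=10)


class TestPairedTTest:
    def test_identical_vectors(self):
        d, p = paired_accuracy_ttest(np.full(10, 0.8), np.full(10, 0.8))
        assert d == 0.0

    def test_constant_shift_closed_form(self, rng):
        base = rng.uniform(0.6, 0.9, 10)
        d, p = paired_accuracy_ttest(base + 0.1, base)
        assert d == pytest.approx(0.1)
        # differences are constant 0.1 -> zero variance, nonzero mean
        assert np.isnan(p)

    def test_textbook_t_formula(self, rng):
        a = rng.uniform(0.6, 0.9, 10)
        b = a - rng.normal(0.05, 0.02, 10)
        d, p = paired_accuracy_ttest(a, b)
        diff = a - b
        t = diff.mean() / (diff.std(ddof=1) / np.sqrt(10))
        expected_p = 2 * sps.t.sf(abs(t), df=9)
        assert p == pytest.approx(expected_p, rel=1e-9)

    def test_symmetric_differences_small_t(self):
        a = np.array([0.8, 0.7, 0.8, 0.7] * 2 + [0.8, 0.7])
        b = np.array([0.7, 0.8, 0.7, 0.8] * 2 + [0.7, 0.8])
        d, p = paired_accuracy_ttest(a, b)
        assert abs(d) < 1e-12
        assert p > 0.9


class TestPermutationImportance:
    def test_predictive_feature_dominates(self, rng):
        table = random_features_table(rng, 60)
        labels = np.repeat(["a", "b"], 30)
        table["speed_median"] = np.where(labels == "a", 0.0, 10.0) + rng.normal(
            0, 0.1, 60
        )
        knn = KNeighborsClassifier(5).fit(table.to_numpy(), labels)
        imp = permutation_importance(table, labels, knn, n_repeats=5, seed=0)
        assert imp.idxmax() == "speed_median"
        assert imp["speed_median"] > 0.3

    def test_reproducible_under_seed(self, rng):
        table = random_features_table(rng, 40)
        labels = np.repeat(["a", "b"], 20)
        knn = KNeighborsClassifier(5).fit(table.to_numpy(), labels)
        i1 = permutation_importance(table, labels, knn, n_repeats=3, seed=9)
        i2 = permutation_importance(table, labels, knn, n_repeats=3, seed=9)
        pd.testing.assert_series_equal(i1, i2)


class TestFeaturesToTable:
    def test_group_column_appended(self, rng):
        m = {
            "speed": rng.uniform(0, 1, 8),
            "curvature": rng.uniform(0, 1, 8),
            "torsion": rng.normal(size=8),
            "shape_change_rate": rng.uniform(0, 1, 7),
            "E_xy": rng.uniform(1, 2, 8),
            "E_xz": rng.uniform(1, 2, 8),
        }
        cells = [
            aggregate_features(cell_id=f"c{i}", group="g1" if i < 2 else "g2", **m)
            for i in range(4)
        ]
        table = features_to_table(cells)
        assert table.shape == (4, 27)
        assert list(table["group"]) == ["g1", "g1", "g2", "g2"]
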