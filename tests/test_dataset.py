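"""Feature-table I/O, balancing, splitting, correlation and PCA."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from trackqc.dataset import (
    DROPPED_BY_DEFAULT,
    FeatureTableError,
    PCATransform,
    balance_classes,
    drop_uninformative,
    pca_fit,
    pca_transform,
    pearson_correlation,
    read_feature_csv,
    split,
    write_feature_csv,
)
from trackqc.features import FEATURE_COLUMNS


def toy_table(n=30, seed=0, accepted_fraction=0.5) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    data = {c: rng.normal(size=n) for c in FEATURE_COLUMNS}
    data["track_count"] = rng.integers(10, 200, size=n).astype(float)
    n_acc = int(round(accepted_fraction * n))
    data["label"] = ["Accepted"] * n_acc + ["Rejected"] * (n - n_acc)
    data["name"] = [f"img_{i}" for i in range(n)]
    return pd.DataFrame(data)


class TestCsvRoundTrip:
    def test_write_then_read_identical(self, tmp_path):
        table = toy_table(3)
        path = write_feature_csv(table, tmp_path / "t.csv")
        back = read_feature_csv(path)
        pd.testing.assert_frame_equal(back[table.columns], table)

    def test_missing_label_column_named_in_error(self, tmp_path):
        table = toy_table(3).drop(columns=["label"])
        table.to_csv(tmp_path / "t.csv", index=False)
        with pytest.raises(FeatureTableError, match="label"):
            read_feature_csv(tmp_path / "t.csv")

    def test_missing_feature_column_named_in_error(self, tmp_path):
        table = toy_table(3).drop(columns=["mean_area"])
        table.to_csv(tmp_path / "t.csv", index=False)
        with pytest.raises(FeatureTableError, match="mean_area"):
            read_feature_csv(tmp_path / "t.csv")

    def test_non_numeric_feature_rejected(self, tmp_path):
        table = toy_table(3)
        table["std_aspect"] = table["std_aspect"].astype(object)
        table.loc[1, "std_aspect"] = "oops"
        table.to_csv(tmp_path / "t.csv", index=False)
        with pytest.raises(FeatureTableError, match="std_aspect"):
            read_feature_csv(tmp_path / "t.csv")

    def test_unknown_label_rejected(self, tmp_path):
        table = toy_table(3)
        table.loc[0, "label"] = "Maybe"
        table.to_csv(tmp_path / "t.csv", index=False)
        with pytest.raises(FeatureTableError, match="label"):
            read_feature_csv(tmp_path / "t.csv")

    def test_label_aliases_normalized(self, tmp_path):
        table = toy_table(4)
        table["label"] = ["accepted", "REJECTED", "1", "0"]
        table.to_csv(tmp_path / "t.csv", index=False)
        back = read_feature_csv(tmp_path / "t.csv")
        assert list(back["label"]) == ["Accepted", "Rejected", "Accepted", "Rejected"]


class TestDropUninformative:
    def test_36_to_34_features(self):
        out = drop_uninformative(toy_table())
        kept = [c for c in FEATURE_COLUMNS if c in out.columns]
        assert len(kept) == 34
        assert not set(DROPPED_BY_DEFAULT) & set(out.columns)

    def test_applying_twice_errors(self):
        once = drop_uninformative(toy_table())
        with pytest.raises(FeatureTableError):
            drop_uninformative(once)

    def test_other_columns_untouched(self):
        table = toy_table()
        out = drop_uninformative(table)
        for col in out.columns:
            pd.testing.assert_series_equal(out[col], table[col])


class TestBalanceClasses:
    def test_forced_toy_counts(self):
        table = toy_table(14, accepted_fraction=10 / 14)
        out = balance_classes(table, rng_seed=0)
        assert len(out) == 8
        assert out["label"].value_counts().to_dict() == {"Accepted": 4, "Rejected": 4}

    def test_output_rows_subset_of_input(self):
        table = toy_table(20, accepted_fraction=0.7)
        out = balance_classes(table, rng_seed=1)
        merged = out.merge(table, how="left", indicator=True)
        assert (merged["_merge"] == "both").all()

    def test_deterministic_under_seed(self):
        table = toy_table(20, accepted_fraction=0.7)
        a = balance_classes(table, rng_seed=5)
        b = balance_classes(table, rng_seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_single_class_rejected(self):
        with pytest.raises(FeatureTableError):
            balance_classes(toy_table(10, accepted_fraction=1.0))


class TestSplit:
    def test_100_rows_split_64_16_20(self):
        parts = split(toy_table(100), rng_seed=0)
        assert [len(p) for p in parts] == [64, 16, 20]

    def test_partition_is_disjoint_and_complete(self):
        table = toy_table(57)
        parts = split(table, rng_seed=1)
        names = [set(p["name"]) for p in parts]
        assert names[0] | names[1] | names[2] == set(table["name"])
        assert not (names[0] & names[1] or names[0] & names[2] or names[1] & names[2])

    def test_stratified_preserves_balance(self):
        table = toy_table(100, accepted_fraction=0.5)
        for part in split(table, rng_seed=2, stratified=True):
            counts = part["label"].value_counts()
            assert abs(counts["Accepted"] - counts["Rejected"]) <= 1

    def test_deterministic_under_seed(self):
        table = toy_table(40)
        for a, b in zip(split(table, rng_seed=3), split(table, rng_seed=3)):
            pd.testing.assert_frame_equal(a, b)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            split(toy_table(10), fractions=(0.5, 0.2, 0.2))


class TestPearsonCorrelation:
    def test_duplicated_column_fully_correlated(self):
        table = toy_table(50)
        table["mean_diameter"] = table["mean_area"]
        corr = pearson_correlation(table)
        assert corr.loc["mean_area", "mean_diameter"] == pytest.approx(1.0)

    def test_independent_columns_nearly_uncorrelated(self):
        table = toy_table(10_000, seed=3)
        corr = pearson_correlation(table)
        off = corr.to_numpy()[~np.eye(len(corr), dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_symmetric_unit_diagonal(self):
        corr = pearson_correlation(toy_table(200))
        arr = corr.to_numpy()
        assert np.allclose(arr, arr.T)
        assert np.allclose(np.diag(arr), 1.0)
        assert np.nanmax(np.abs(arr)) <= 1.0 + 1e-12


class TestPCA:
    def test_components_orthonormal(self):
        pca = pca_fit(drop_uninformative(toy_table(60)))
        gram = pca.components @ pca.components.T
        assert np.allclose(gram, np.eye(gram.shape[0]), atol=1e-8)

    def test_variance_target_one_keeps_all_components(self):
        pca = pca_fit(drop_uninformative(toy_table(60)), variance_target=1.0)
        assert pca.n_components == 34

    def test_explained_variance_fractions_monotone(self):
        pca = pca_fit(drop_uninformative(toy_table(80)))
        ratios = pca.explained_variance_ratio
        assert np.all(np.diff(ratios) <= 1e-12)
        cum = np.cumsum(ratios)
        assert np.all(np.diff(cum) >= -1e-12)
        assert cum[-1] <= 1.0 + 1e-9

    def test_correlated_features_compress(self):
        rng = np.random.default_rng(4)
        base = rng.normal(size=(200, 4))
        data = {}
        for i, c in enumerate(FEATURE_COLUMNS):
            data[c] = base[:, i % 4] + 0.001 * rng.normal(size=200)
        data.update(track_count=np.ones(200), label=["Accepted"] * 100 + ["Rejected"] * 100,
                    name=[str(i) for i in range(200)])
        pca = pca_fit(drop_uninformative(pd.DataFrame(data)), variance_target=0.999)
        assert pca.n_components <= 8

    def test_transform_of_training_mean_is_zero(self):
        table = drop_uninformative(toy_table(60))
        pca = pca_fit(table)
        mean_row = table.copy().iloc[[0]]
        for c in pca.feature_names:
            mean_row[c] = pca.center[list(pca.feature_names).index(c)]
        assert np.allclose(pca_transform(pca, mean_row), 0.0, atol=1e-10)

    def test_full_reconstruction(self):
        table = drop_uninformative(toy_table(50, seed=9))
        pca = pca_fit(table, variance_target=1.0)
        x = table.loc[:, list(pca.feature_names)].to_numpy()
        z = (x - pca.center) / pca.scale
        proj = pca_transform(pca, table, n_components=len(pca.feature_names))
        assert np.allclose(proj @ pca.components, z, atol=1e-8)

    def test_constant_column_guard(self):
        table = toy_table(30)
        table["mean_area"] = 5.0
        pca = pca_fit(drop_uninformative(table))
        assert np.all(np.isfinite(pca.components))

    def test_json_round_trip(self, tmp_path):
        pca = pca_fit(drop_uninformative(toy_table(40)))
        path = pca.to_json(tmp_path / "pca.json")
        back = PCATransform.from_json(path)
        assert back.feature_names == pca.feature_names
        assert np.allclose(back.components, pca.components)
        assert back.n_components == pca.n_components

    def test_feature_mismatch_rejected(self):
        pca = pca_fit(drop_uninformative(toy_table(40)))
        with pytest.raises(FeatureTableError):
            pca_transform(pca, drop_uninformative(toy_table(5)).drop(columns=["mean_area"]))


def test_full_preprocessing_chain_reproducible():
    table = toy_table(120, seed=11, accepted_fraction=0.6)

    def run():
        t = drop_uninformative(table)
        t = balance_classes(t, rng_seed=21)
        train_t, val_t, test_t = split(t, rng_seed=22)
        pca = pca_fit(train_t)
        return pca_transform(pca, val_t)

    assert np.array_equal(run(), run())
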