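"""Labelling, splitting, scaling, PCA, resampling and the six variants."""

import numpy as np
import pandas as pd
import pytest

from hotspots.preprocessing import (
    LABEL_COLUMN,
    PreprocessState,
    VARIANT_NAMES,
    VarianceThresholdPCA,
    ZScoreScaler,
    build_variants,
    dataset_composition,
    downsample_major,
    feature_columns,
    label_from_ddg,
    load_feature_table,
    stratified_split,
    upsample_minor,
)
from hotspots.synthetic import make_curated_style_table, make_synthetic_table


class TestLabelling:
    @pytest.mark.parametrize(
        "ddg,expected",
        [(2.0, "HS"), (1.99, "NS"), (-0.5, "NS"), (5.3, "HS")],
    )
    def test_threshold_boundary_inclusive(self, ddg, expected):
        assert label_from_ddg(ddg) == expected

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            label_from_ddg(float("nan"))

    def test_loader_derives_labels_and_drops_missing(self, tmp_path):
        table, _ = make_synthetic_table(n_obs=30, seed=3)
        raw = table.drop(columns=[LABEL_COLUMN])
        raw.loc[0, "ddg"] = np.nan
        path = tmp_path / "t.csv"
        raw.to_csv(path, index=False)
        loaded = load_feature_table(path)
        assert len(loaded) == 29
        assert set(loaded[LABEL_COLUMN]) <= {"HS", "NS"}
        assert (loaded[LABEL_COLUMN] == "HS").equals(loaded["ddg"] >= 2.0)


class TestStratifiedSplit:
    def test_printed_split_arithmetic(self):
        """127 HS + 407 NS at 70% -> 374 train (89+285) and 160 test."""
        table, _ = make_curated_style_table(seed=0, n_features=5,
                                                  n_informative=2)
        train, test = stratified_split(table, 0.7, seed=11)
        assert len(train) == 374 and len(test) == 160
        assert (train[LABEL_COLUMN] == "HS").sum() == 89
        assert (train[LABEL_COLUMN] == "NS").sum() == 285

    def test_balanced_small_split(self):
        table, _ = make_synthetic_table(n_obs=10, hs_fraction=0.5, seed=1,
                                        exact_counts=True)
        train, test = stratified_split(table, 0.5, seed=0)
        assert len(train) == len(test) == 5

    def test_partition_is_disjoint_and_exhaustive(self, labelled_table):
        table, _ = labelled_table
        train, test = stratified_split(table, 0.7, seed=5)
        key = ["complex", "residue"]
        all_ids = set(map(tuple, table[key].to_numpy()))
        train_ids = set(map(tuple, train[key].to_numpy()))
        test_ids = set(map(tuple, test[key].to_numpy()))
        assert train_ids | test_ids == all_ids
        assert train_ids & test_ids == set()

    def test_deterministic_under_seed(self, labelled_table):
        table, _ = labelled_table
        a1, _ = stratified_split(table, 0.7, seed=3)
        a2, _ = stratified_split(table, 0.7, seed=3)
        b, _ = stratified_split(table, 0.7, seed=4)
        pd.testing.assert_frame_equal(a1, a2)
        assert not a1.equals(b)
        assert (b[LABEL_COLUMN] == "HS").sum() == (a1[LABEL_COLUMN] == "HS").sum()

    def test_single_class_rejected(self):
        table, _ = make_synthetic_table(n_obs=20, hs_fraction=0.0, seed=0)
        with pytest.raises(ValueError):
            stratified_split(table, 0.7, seed=0)


class TestScaler:
    def test_hand_computed_z_scores(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        scaler = ZScoreScaler().fit(X)
        out = scaler.transform(X)
        assert out["a"].tolist() == pytest.approx([-1.0, 0.0, 1.0])  # sd(ddof=1)=1

    def test_constant_column_dropped_and_recorded(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [7.0, 7.0, 7.0]})
        scaler = ZScoreScaler().fit(X)
        assert scaler.dropped_ == ["b"]
        assert "b" not in scaler.transform(X).columns

    def test_test_row_at_train_mean_maps_to_zero(self):
        train = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        scaler = ZScoreScaler().fit(train)
        out = scaler.transform(pd.DataFrame({"a": [2.0]}))
        assert out["a"].iloc[0] == pytest.approx(0.0)

    def test_train_round_trip_centred(self, labelled_table):
        table, _ = labelled_table
        X = table[feature_columns(table)]
        out = ZScoreScaler().fit(X).transform(X)
        assert np.abs(out.mean(axis=0)).max() < 1e-9
        assert out.std(axis=0, ddof=1).to_numpy() == pytest.approx(1.0)

    def test_all_constant_rejected(self):
        with pytest.raises(ValueError):
            ZScoreScaler().fit(pd.DataFrame({"a": [1.0, 1.0]}))


class TestPca:
    def test_equal_eigenvalues_need_all_components(self, rng):
        X = rng.standard_normal((500, 3))
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        pca = VarianceThresholdPCA(threshold=0.95).fit(X)
        assert pca.n_components_ == 3

    def test_rank_one_dominated_matrix_keeps_one(self, rng):
        u = rng.standard_normal(200)
        X = np.outer(u, [1.0, 2.0, -1.0]) + 0.01 * rng.standard_normal((200, 3))
        pca = VarianceThresholdPCA(threshold=0.95).fit(X)
        assert pca.n_components_ == 1

    def test_minimality_of_retained_count(self, rng):
        """d is the smallest count reaching the cumulative-variance bar."""
        X = rng.standard_normal((100, 8)) @ np.diag([5, 4, 3, 2, 1, 0.5, 0.2, 0.1])
        pca = VarianceThresholdPCA(threshold=0.95).fit(X)
        ratios = np.cumsum(pca.pca_.explained_variance_ratio_)
        d = pca.n_components_
        assert ratios[d - 1] >= 0.95
        assert d == 1 or ratios[d - 2] < 0.95

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            VarianceThresholdPCA(threshold=1.5).fit(np.eye(3))


class TestResampling:
    def test_upsample_counts_and_majority_preserved(self):
        table, _ = make_curated_style_table(seed=0, n_features=5,
                                                  n_informative=2)
        train, _ = stratified_split(table, 0.7, seed=1)
        up = upsample_minor(train, seed=2)
        counts = up[LABEL_COLUMN].value_counts()
        assert counts["HS"] == counts["NS"] == 285
        majority = train[train[LABEL_COLUMN] == "NS"]
        pd.testing.assert_frame_equal(
            up[up[LABEL_COLUMN] == "NS"].reset_index(drop=True),
            majority.reset_index(drop=True),
        )
        # added rows are copies of original minority rows
        minor_ids = set(train.loc[train[LABEL_COLUMN] == "HS", "residue"])
        assert set(up.loc[up[LABEL_COLUMN] == "HS", "residue"]) <= minor_ids

    def test_downsample_counts_and_subset(self):
        table, _ = make_curated_style_table(seed=0, n_features=5,
                                                  n_informative=2)
        train, _ = stratified_split(table, 0.7, seed=1)
        down = downsample_major(train, seed=2)
        counts = down[LABEL_COLUMN].value_counts()
        assert counts["HS"] == counts["NS"] == 89
        train_ids = set(train["residue"])
        assert set(down["residue"]) <= train_ids
        assert not down["residue"].duplicated().any()

    def test_balanced_input_unchanged(self):
        table, _ = make_synthetic_table(n_obs=40, hs_fraction=0.5, seed=5,
                                        exact_counts=True)
        assert len(upsample_minor(table, 0)) == 40
        assert len(downsample_major(table, 0)) == 40

    def test_single_class_rejected(self):
        table, _ = make_synthetic_table(n_obs=20, hs_fraction=0.0, seed=0)
        with pytest.raises(ValueError):
            upsample_minor(table, 0)


@pytest.fixture(scope="module")
def variants(labelled_table):
    table, _ = labelled_table
    train, test = stratified_split(table, 0.7, seed=9)
    return build_variants(train, test, seed=9), train


class TestVariants:
    def test_exactly_six_named_variants(self, variants):
        v, _ = variants
        assert tuple(v) == VARIANT_NAMES

    def test_scaled_is_scaling_only(self, variants):
        v, train = variants
        scaled = v["Scaled"]
        assert len(scaled.train) == len(train)
        feats = feature_columns(scaled.train)
        assert np.abs(scaled.train[feats].mean(0)).max() < 1e-9

    def test_resampled_variants_balanced(self, variants):
        v, _ = variants
        for name in ("ScaledUp", "PCAUp"):
            counts = v[name].train[LABEL_COLUMN].value_counts()
            assert counts["HS"] == counts["NS"]
        for name in ("ScaledDown", "PCADown"):
            counts = v[name].train[LABEL_COLUMN].value_counts()
            assert counts["HS"] == counts["NS"]

    def test_pca_variants_use_components(self, variants):
        v, _ = variants
        feats = feature_columns(v["PCA"].train)
        assert all(c.startswith("PC") for c in feats)
        assert v["PCA"].state.pca.cumulative_ratio_ >= 0.95

    def test_test_tables_share_train_statistics(self, variants):
        v, _ = variants
        # test transformed with train stats: means not exactly zero
        feats = feature_columns(v["Scaled"].test)
        assert np.abs(v["Scaled"].test[feats].mean(0)).max() > 1e-9


class TestPreprocessState:
    def test_json_round_trip_reproduces_transform(self, labelled_table):
        table, _ = labelled_table
        train, test = stratified_split(table, 0.7, seed=2)
        variants = build_variants(train, test, seed=2)
        for name in ("Scaled", "PCA"):
            state = variants[name].state
            again = PreprocessState.from_json(state.to_json())
            a = state.transform(test)
            b = again.transform(test)
            pd.testing.assert_frame_equal(a, b)

    def test_schema_mismatch_lists_missing_features(self, labelled_table):
        table, _ = labelled_table
        train, test = stratified_split(table, 0.7, seed=2)
        state = build_variants(train, test, seed=2)["Scaled"].state
        broken = test.drop(columns=feature_columns(test)[:2])
        with pytest.raises(ValueError, match="schema mismatch"):
            state.transform(broken)

    def test_version_check(self):
        with pytest.raises(ValueError, match="version"):
            PreprocessState.from_json('{"version": "99"}')


def test_dataset_composition_bookkeeping():
    table, _ = make_curated_style_table(seed=1)
    comp = dataset_composition(table)
    assert comp == {
        "n_observations": 534, "n_complexes": 53,
        "n_hs": 127, "n_ns": 407, "n_features": 881,
    }
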