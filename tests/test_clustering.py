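import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_rand_score
from sklearn.preprocessing import StandardScaler

from folliclemap import (
    FAMD,
    WardClusterer,
    build_mixed_matrix,
    club_subtype_split,
    gower_matrix,
    subtype_comparison,
)


class TestGower:
    def test_identical_rows_have_zero_distance(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 5.0], "f": [True, True, False]})
        D = gower_matrix(df)
        assert D[0, 1] == 0.0
        assert np.allclose(D, D.T) and np.all(np.diag(D) == 0)

    def test_opposite_extremes_have_distance_one(self):
        df = pd.DataFrame(
            {"a": [0.0, 10.0], "b": [5.0, -5.0], "f": [True, False],
             "g": [False, True]})
        assert gower_matrix(df)[0, 1] == pytest.approx(1.0)

    def test_hand_computed_mixed_example(self):
        # continuous ranges 5 and 20 -> dissims 1 and 1; flags equal, unequal
        df = pd.DataFrame(
            {"a": [0.0, 5.0], "b": [10.0, 30.0], "f": [True, True],
             "g": [False, True]})
        assert gower_matrix(df)[0, 1] == pytest.approx((1 + 1 + 0 + 1) / 4)

    def test_invariant_to_affine_rescaling_of_continuous_columns(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {"a": rng.normal(size=12), "b": rng.uniform(size=12),
             "f": rng.random(12) > 0.5})
        D0 = gower_matrix(df)
        scaled = df.copy()
        scaled["a"] = 1000.0 * scaled["a"] - 42.0
        scaled["b"] = -3.0 * scaled["b"]
        np.testing.assert_allclose(gower_matrix(scaled), D0, atol=1e-12)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            gower_matrix(pd.DataFrame({"a": [1.0]}))


class TestFAMD:
    def test_all_continuous_equals_standardized_pca(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(25, 5)), columns=list("abcde"))
        coords = FAMD(n_components=5).fit(X).row_coordinates_
        scores = PCA(n_components=5).fit_transform(StandardScaler().fit_transform(X))
        for j in range(5):
            assert (
                np.allclose(coords[:, j], scores[:, j], atol=1e-8)
                or np.allclose(coords[:, j], -scores[:, j], atol=1e-8)
            )

    def test_duplicated_rows_get_duplicated_coordinates(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame({"a": rng.normal(size=10), "f": rng.random(10) > 0.5})
        X2 = pd.concat([X, X.iloc[[3]]], ignore_index=True)
        coords = FAMD(n_components=2).fit(X2).row_coordinates_
        np.testing.assert_allclose(coords[3], coords[-1], atol=1e-12)

    def test_inertia_fractions_sum_to_one(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(
            {"a": rng.normal(size=15), "b": rng.normal(size=15),
             "f": rng.random(15) > 0.3})
        model = FAMD(n_components=2).fit(X)
        assert model.explained_inertia_.sum() == pytest.approx(1.0)

    def test_constant_continuous_column_named_in_error(self):
        X = pd.DataFrame({"a": np.ones(10), "b": np.arange(10.0)})
        with pytest.raises(ValueError, match="'a'"):
            FAMD().fit(X)

    def test_single_category_binary_dropped_with_warning(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame({"a": rng.normal(size=10), "f": np.full(10, True)})
        with pytest.warns(UserWarning, match="single category"):
            model = FAMD(n_components=1).fit(X)
        assert model.binary_ == []


class TestWard:
    def test_two_planted_blobs_recovered(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 0.1, size=(20, 2))
        b = rng.normal(5, 0.1, size=(20, 2))
        df = pd.DataFrame(np.vstack([a, b]), columns=["x", "y"])
        labels = WardClusterer(n_clusters=2).fit_predict(gower_matrix(df))
        truth = np.repeat([0, 1], 20)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_coincident_pair_merges_first_at_zero_height(self):
        df = pd.DataFrame({"x": [0.0, 0.0, 10.0], "y": [1.0, 1.0, 5.0]})
        model = WardClusterer(n_clusters=2).fit(gower_matrix(df))
        first = model.linkage_[0]
        assert sorted(first[:2]) == [0, 1]
        assert first[2] == 0.0
        assert np.all(np.diff(model.linkage_[:, 2]) >= 0)

    def test_row_permutation_equivariance(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(rng.normal(size=(15, 3)), columns=list("xyz"))
        labels = WardClusterer(n_clusters=3).fit_predict(gower_matrix(df))
        perm = rng.permutation(15)
        labels_p = WardClusterer(n_clusters=3).fit_predict(
            gower_matrix(df.iloc[perm].reset_index(drop=True)))
        assert adjusted_rand_score(labels[perm], labels_p) == 1.0

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0.0, 1.0], [0.5, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            WardClusterer().fit(D)


class TestSubtypes:
    def test_identical_groups_give_p_one(self):
        v = np.tile([1.0, 2.0, 3.0], 2)
        labels = np.repeat([0, 1], 3)
        res = subtype_comparison(labels, {"v": v})
        assert res.table.loc[0, "p_value"] == pytest.approx(1.0)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(7)
        v = rng.normal(size=20)
        labels = rng.integers(0, 2, 20)
        while len(np.unique(labels)) != 2 or min(labels.sum(), 20 - labels.sum()) < 2:
            labels = rng.integers(0, 2, 20)
        p1 = subtype_comparison(labels, {"v": v}).table.loc[0, "p_value"]
        p2 = subtype_comparison(1 - labels, {"v": v}).table.loc[0, "p_value"]
        assert p1 == pytest.approx(p2)

    def test_requires_two_groups_with_members(self):
        with pytest.raises(ValueError):
            subtype_comparison(np.zeros(6), {"v": np.arange(6.0)})
        with pytest.raises(ValueError):
            subtype_comparison(np.array([0, 0, 0, 0, 0, 1]), {"v": np.arange(6.0)})

    def test_club_split_recovers_planted_subtypes(self, small_follicle):
        config, _, features, truth = small_follicle
        club, labels = club_subtype_split(features)
        true_sub = truth.loc[club.index, "true_club_subtype"].to_numpy()
        assert adjusted_rand_score(true_sub, labels) >= 0.9


def test_axonal_and_morphological_gower_correlate(small_follicle):
    """Both dissimilarity views share type structure (Mantel permutation test)."""
    _, _, features, _ = small_follicle
    typed = features[
        features["myelinated"] & ~features["superficial"]
        & (features["afferent_type"] != "Unclassified")
    ]
    Da = gower_matrix(build_mixed_matrix(typed, mode="axonal"))
    Dm = gower_matrix(build_mixed_matrix(typed, mode="morphological"))
    n = Da.shape[0]
    iu = np.triu_indices(n, k=1)
    r_obs = sps.pearsonr(Da[iu], Dm[iu])[0]
    assert r_obs > 0
    rng = np.random.default_rng(8)
    null = []
    for _ in range(199):
        perm = rng.permutation(n)
        null.append(sps.pearsonr(Da[np.ix_(perm, perm)][iu], Dm[iu])[0])
    p = (1 + np.sum(np.asarray(null) >= r_obs)) / 200
    assert p < 0.05
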