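"""Tests for the three feature-ranking methods and the iterated selection
protocol, cross-checked against independent library implementations."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from sklearn.metrics import mutual_info_score as sk_mi

from mipower import (
    FEATURE_NAMES,
    FeatureMatrix,
    chi_square_score,
    correlation_coefficient,
    correlation_map,
    discard_correlated,
    mutual_information_score,
    rank_features,
)
from mipower.ranking import equal_frequency_bins

from conftest import informative_matrix


def fm_from_values(values, labels):
    return FeatureMatrix(
        features=pd.DataFrame(values, columns=list(FEATURE_NAMES)),
        labels=np.asarray(labels),
    )


class TestBinning:
    def test_equal_frequency_bins_balanced(self):
        x = np.arange(100, dtype=float)
        bins = equal_frequency_bins(x, 4)
        _, counts = np.unique(bins, return_counts=True)
        assert len(counts) == 4
        assert counts.max() - counts.min() <= 1

    def test_ties_collapse_bins(self):
        x = np.array([0.0] * 50 + [1.0] * 50)
        assert len(np.unique(equal_frequency_bins(x, 4))) == 2


class TestMutualInformation:
    def test_perfect_binary_dependency_is_ln2(self):
        y = np.array(["hand", "feet"] * 50)
        x = (y == "feet").astype(float)
        assert mutual_information_score(x, y) == pytest.approx(np.log(2), abs=1e-12)

    def test_independent_feature_scores_near_zero(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(2000)
        y = np.array(["hand", "feet"] * 1000)
        assert mutual_information_score(x, y, n_bins=4) <= 0.02

    def test_constant_feature_warns_and_scores_zero(self):
        y = np.array(["hand", "feet"] * 10)
        with pytest.warns(RuntimeWarning, match="constant"):
            assert mutual_information_score(np.ones(20), y) == 0.0

    def test_matches_sklearn_on_binned_data(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(500)
        y = rng.choice(["hand", "feet"], 500)
        ours = mutual_information_score(x, y, n_bins=4)
        theirs = sk_mi(equal_frequency_bins(x, 4), y)
        assert ours == pytest.approx(theirs, abs=1e-12)

    @given(scale=st.floats(0.1, 100.0), shift=st.floats(-50.0, 50.0))
    @settings(max_examples=20, deadline=None)
    def test_invariant_to_affine_rescaling(self, scale, shift):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(300)
        y = np.array(["hand", "feet"] * 150)
        base = mutual_information_score(x, y)
        assert mutual_information_score(scale * x + shift, y) == pytest.approx(
            base, abs=1e-9
        )


class TestChiSquare:
    def test_diagonal_table_statistic_20(self):
        """Feature binned into 2 bins aligned with the labels gives the
        [[10, 0], [0, 10]] table: statistic 4 x 25 / 5 = 20."""
        y = np.array(["hand"] * 10 + ["feet"] * 10)
        x = np.array([0.0] * 10 + [1.0] * 10)
        result = chi_square_score(x, y, n_bins=2)
        assert result.statistic == pytest.approx(20.0)
        assert result.alpha == 0.05

    def test_observed_equals_expected_gives_zero(self):
        # two bins, each holding both classes equally
        x = np.array([0.0, 0.0, 1.0, 1.0] * 5)
        y = np.array(["hand", "feet", "hand", "feet"] * 5)
        result = chi_square_score(x, y, n_bins=2)
        assert result.statistic == pytest.approx(0.0)
        assert result.p_value == pytest.approx(1.0)

    def test_matches_scipy_contingency(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(400)
        y = rng.choice(["hand", "feet"], 400)
        ours = chi_square_score(x, y, n_bins=4)
        bins = equal_frequency_bins(x, 4)
        table = pd.crosstab(bins, y).to_numpy()
        ref_stat, ref_p, ref_dof, _ = stats.chi2_contingency(table, correction=False)
        assert ours.statistic == pytest.approx(ref_stat, rel=1e-12)
        assert ours.p_value == pytest.approx(ref_p, rel=1e-9)
        assert ours.dof == ref_dof

    @given(scale=st.floats(0.1, 100.0), shift=st.floats(-50.0, 50.0))
    @settings(max_examples=20, deadline=None)
    def test_invariant_to_affine_rescaling(self, scale, shift):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(300)
        y = np.array(["hand", "feet"] * 150)
        base = chi_square_score(x, y).statistic
        assert chi_square_score(scale * x + shift, y).statistic == pytest.approx(
            base, abs=1e-9
        )


class TestCorrelation:
    def test_positive_affine_relation_gives_one(self):
        a = np.array([1.0, 2.0, 5.0, 7.0])
        assert correlation_coefficient(a, 2 * a + 3) == pytest.approx(1.0)

    def test_perfect_negative(self):
        assert correlation_coefficient(
            np.array([1.0, 2.0, 3.0]), np.array([6.0, 4.0, 2.0])
        ) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        r = correlation_coefficient(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 4.0]))
        assert r == pytest.approx(0.9820, abs=5e-5)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            correlation_coefficient(np.ones(5), np.arange(5.0))

    def test_matches_scipy_pearsonr(self):
        rng = np.random.default_rng(5)
        a, b = rng.standard_normal((2, 200))
        ours = correlation_coefficient(a, b)
        assert ours == pytest.approx(stats.pearsonr(a, b)[0], abs=1e-12)


class TestCorrelationMap:
    def test_diagonal_is_one_and_symmetric(self):
        rng = np.random.default_rng(6)
        fm = fm_from_values(rng.standard_normal((100, 11)), ["hand", "feet"] * 50)
        cmap = correlation_map(fm)
        mat = cmap.matrix.to_numpy()
        np.testing.assert_allclose(np.diag(mat), 1.0)
        np.testing.assert_allclose(mat, mat.T)
        assert np.abs(mat).max() <= 1.0

    def test_duplicate_column_listed_at_one(self):
        rng = np.random.default_rng(7)
        values = rng.standard_normal((100, 11))
        values[:, 4] = values[:, 0]  # duplicate feature 5 of feature 1
        cmap = correlation_map(fm_from_values(values, ["hand", "feet"] * 50))
        assert any(
            {i, j} == {1, 5} and r == pytest.approx(1.0) for i, j, r in cmap.pairs
        )

    def test_independent_columns_have_no_pairs(self):
        rng = np.random.default_rng(8)
        fm = fm_from_values(rng.standard_normal((1000, 11)), ["hand", "feet"] * 500)
        assert correlation_map(fm, threshold=0.85).pairs == []

    def test_constant_column_warns_and_zeroes(self):
        rng = np.random.default_rng(9)
        values = rng.standard_normal((50, 11))
        values[:, 2] = 1.0
        with pytest.warns(RuntimeWarning, match="constant"):
            cmap = correlation_map(fm_from_values(values, ["hand", "feet"] * 25))
        col = cmap.matrix.to_numpy()[2]
        assert col[2] == 1.0
        assert not np.delete(col, 2).any()


class TestDiscardCorrelated:
    def test_all_survive_without_pairs(self):
        rng = np.random.default_rng(10)
        fm = fm_from_values(rng.standard_normal((500, 11)), ["hand", "feet"] * 250)
        cmap = correlation_map(fm)
        assert discard_correlated(cmap) == list(range(1, 12))

    def test_single_pair_drops_more_redundant_member(self):
        rng = np.random.default_rng(11)
        values = rng.standard_normal((500, 11))
        # feature 2 duplicates feature 1 but also correlates with feature 3,
        # making it the more redundant of the pair
        values[:, 1] = values[:, 0] + 0.01 * rng.standard_normal(500)
        values[:, 2] = 0.5 * values[:, 1] + 0.9 * values[:, 2]
        cmap = correlation_map(fm_from_values(values, ["hand", "feet"] * 250))
        survivors = discard_correlated(cmap)
        assert 2 not in survivors
        assert 1 in survivors

    def test_triplicated_column_keeps_exactly_one(self):
        rng = np.random.default_rng(12)
        values = rng.standard_normal((300, 11))
        values[:, 5] = values[:, 0]
        values[:, 9] = values[:, 0]
        cmap = correlation_map(fm_from_values(values, ["hand", "feet"] * 150))
        survivors = discard_correlated(cmap)
        assert len(set(survivors) & {1, 6, 10}) == 1
        assert len(survivors) == 9


class TestRankFeatures:
    def test_default_selection_sizes_and_iterations(self):
        fm = informative_matrix(0)
        mi = rank_features(fm, method="mutual_information")
        chi = rank_features(fm, method="chi_square")
        assert len(mi.selected) == 6 and mi.n_iterations == 10
        assert len(chi.selected) == 5 and chi.n_iterations == 10

    def test_ranks_are_permutations(self):
        fm = informative_matrix(1)
        result = rank_features(fm, method="chi_square", seed=3)
        for _, row in result.per_iteration_ranks.iterrows():
            assert sorted(row) == list(range(1, 12))

    def test_label_copy_feature_always_selected(self):
        fm = informative_matrix(2)
        values = fm.values.copy()
        values[:, 7] = (fm.labels == "feet").astype(float)  # feature 8
        fm2 = fm_from_values(values, fm.labels)
        for method in ("mutual_information", "chi_square"):
            result = rank_features(fm2, method=method, seed=4)
            assert 8 in result.selected
            assert (result.per_iteration_ranks.iloc[:, 7] == 1).all()

    def test_reproducible_from_seed(self):
        fm = informative_matrix(3)
        a = rank_features(fm, method="mutual_information", seed=5)
        b = rank_features(fm, method="mutual_information", seed=5)
        assert a.selected == b.selected
        pd.testing.assert_frame_equal(a.per_iteration_scores, b.per_iteration_scores)

    def test_affine_rescaling_preserves_selection(self):
        fm = informative_matrix(4)
        base = rank_features(fm, method="chi_square", seed=6)
        rescaled = fm_from_values(3.0 * fm.values + 7.0, fm.labels)
        again = rank_features(rescaled, method="chi_square", seed=6)
        assert base.selected == again.selected

    def test_informative_features_recovered(self):
        """3 informative + 8 noise features: both MI and chi-square
        selections contain all informative indices."""
        fm = informative_matrix(5)
        mi = rank_features(fm, method="mutual_information", seed=7)
        chi = rank_features(fm, method="chi_square", seed=7)
        assert {2, 5, 9} <= set(mi.selected)
        assert {2, 5, 9} <= set(chi.selected)

    def test_dependency_scores_beat_noise(self):
        """MI and chi-square of a label-copy feature exceed any noise
        feature's score for n >= 200."""
        rng = np.random.default_rng(13)
        n = 200
        labels = np.array(["hand", "feet"] * (n // 2))
        values = rng.standard_normal((n, 11))
        values[:, 0] = (labels == "feet").astype(float)
        mi_scores = [
            mutual_information_score(values[:, j], labels) for j in range(11)
        ]
        chi_scores = [
            chi_square_score(values[:, j], labels).statistic for j in range(11)
        ]
        assert mi_scores[0] > max(mi_scores[1:])
        assert chi_scores[0] > max(chi_scores[1:])

    def test_correlation_method_returns_survivors(self):
        rng = np.random.default_rng(14)
        values = rng.standard_normal((400, 11))
        values[:, 6] = values[:, 1] + 0.01 * rng.standard_normal(400)
        fm = fm_from_values(values, ["hand", "feet"] * 200)
        result = rank_features(fm, method="correlation", seed=8)
        assert len(result.selected) == 10
        # one of the duplicated pair {2, 7} is gone
        assert len(set(result.selected) & {2, 7}) == 1

    @pytest.mark.parametrize("bad", [{"method": "anova"}, {"k": 0}, {"k": 12}])
    def test_invalid_arguments_rejected(self, bad):
        fm = informative_matrix(6, n=60)
        kwargs = {"method": "mutual_information", **bad}
        with pytest.raises(ValueError):
            rank_features(fm, **kwargs)
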