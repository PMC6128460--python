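"""Dominance, front-peeling ranks, composites, and ranking invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from paretoprior import (
    ParetoRanker,
    RankAssignment,
    check_weighted_consistency,
    composite_pareto_rank_array,
    non_dominated_mask,
    pareto_rank_array,
    weakly_dominates,
)

from conftest import oracle_nds_indices, oracle_pareto_ranks


class TestWeakDominance:
    @pytest.mark.parametrize(
        "u, v, expected",
        [
            ((1, 2), (1, 3), True),  # equality allowed with one strict improvement
            ((1, 2), (1, 2), False),  # identical vectors never dominate
            ((1, 4), (2, 2), False),  # trade-off: mutually non-dominated
            ((2, 2), (1, 4), False),
            ((0, 0), (1, 1), True),
            ((3,), (3,), False),
        ],
    )
    def test_definition(self, u, v, expected):
        assert weakly_dominates(u, v) is expected

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            weakly_dominates((1, 2), (1, 2, 3))

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            weakly_dominates((1, np.nan), (1, 2))

    def test_antisymmetric_and_irreflexive(self, rng):
        X = rng.random((30, 3))
        for i in range(len(X)):
            assert not weakly_dominates(X[i], X[i])
            for j in range(i):
                assert not (weakly_dominates(X[i], X[j]) and weakly_dominates(X[j], X[i]))


class TestNonDominatedSet:
    def test_duplicates_both_included(self):
        X = np.array([(1, 4), (2, 2), (4, 1), (3, 3), (4, 4), (2, 2)], dtype=float)
        mask = non_dominated_mask(X)
        assert list(np.nonzero(mask)[0]) == [0, 1, 2, 5]

    def test_single_row_is_front(self):
        assert non_dominated_mask([[7, 7]]).tolist() == [True]

    def test_dominated_row_excluded(self):
        assert non_dominated_mask([[0, 0], [1, 1]]).tolist() == [True, False]

    def test_matches_all_pairs_oracle(self, rng):
        X = rng.integers(0, 8, size=(60, 3)).astype(float)
        assert list(np.nonzero(non_dominated_mask(X))[0]) == oracle_nds_indices(X)


class TestParetoRank:
    def test_worked_example(self):
        X = np.array([(1, 4), (2, 2), (4, 1), (3, 3), (4, 4), (2, 2)], dtype=float)
        assert pareto_rank_array(X).tolist() == [1, 1, 1, 2, 3, 1]

    def test_single_criterion_is_dense_ranking(self):
        assert pareto_rank_array(np.array([[3.0], [1.0], [2.0]])).tolist() == [3, 1, 2]

    def test_all_identical_rows_share_rank_one(self):
        X = np.ones((5, 3))
        assert pareto_rank_array(X).tolist() == [1] * 5

    def test_dominance_implies_strict_rank_order(self, rng):
        X = rng.integers(0, 6, size=(80, 3)).astype(float)
        ranks = pareto_rank_array(X)
        for i in range(len(X)):
            for j in range(len(X)):
                if i != j and weakly_dominates(X[i], X[j]):
                    assert ranks[i] < ranks[j]

    def test_ranks_contiguous_from_one(self, rng):
        X = rng.random((100, 4))
        ranks = pareto_rank_array(X)
        assert set(np.unique(ranks)) == set(range(1, ranks.max() + 1))

    def test_permutation_invariance(self, rng):
        X = rng.random((120, 3))
        perm = rng.permutation(len(X))
        assert np.array_equal(pareto_rank_array(X)[perm], pareto_rank_array(X[perm]))

    def test_monotone_transform_of_one_column_preserves_ranks(self, rng):
        X = rng.random((80, 4))
        Y = X.copy()
        Y[:, 2] = X[:, 2] ** 3
        assert np.array_equal(pareto_rank_array(X), pareto_rank_array(Y))

    def test_positive_column_weights_preserve_ranks(self, rng):
        X = rng.random((80, 4))
        w = np.array([0.1, 10.0, 3.5, 0.7])
        assert np.array_equal(pareto_rank_array(X), pareto_rank_array(X * w))

    def test_anticorrelated_distinct_pairs_all_rank_one(self, rng):
        x = rng.permutation(50).astype(float)
        X = np.column_stack([x, -x])
        assert pareto_rank_array(X).max() == 1

    def test_duplicated_column_reduces_to_dense_ranking(self, rng):
        x = rng.integers(0, 20, size=60).astype(float)
        X = np.column_stack([x, x])
        dense = pareto_rank_array(x[:, None])
        assert np.array_equal(pareto_rank_array(X), dense)

    def test_nan_rows_unranked_but_rest_contiguous(self):
        X = np.array([[1, 1], [np.nan, 2], [2, 2], [3, 3]])
        ranks = pareto_rank_array(X)
        assert ranks[1] == 0
        assert ranks[[0, 2, 3]].tolist() == [1, 2, 3]

    def test_all_nan_rejected(self):
        with pytest.raises(ValueError, match="no valid"):
            pareto_rank_array(np.full((3, 2), np.nan))

    def test_infinite_rejected(self):
        with pytest.raises(ValueError, match="infinit"):
            pareto_rank_array(np.array([[1.0, np.inf]]))

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        arrays(
            float,
            st.tuples(st.integers(1, 40), st.integers(1, 4)),
            elements=st.integers(0, 6).map(float),
        )
    )
    def test_matches_brute_force_oracle(self, X):
        assert np.array_equal(pareto_rank_array(X), oracle_pareto_ranks(X))


class TestParetoRankerEstimator:
    def test_fit_predict_and_attributes(self):
        est = ParetoRanker()
        ranks = est.fit_predict([[1, 4], [2, 2], [3, 3]])
        assert ranks.tolist() == [1, 1, 2]
        assert est.max_rank_ == 2
        assert est.n_features_in_ == 2
        assert np.array_equal(est.predict(), ranks)

    def test_on_missing_raise(self):
        with pytest.raises(ValueError, match="NaN"):
            ParetoRanker(on_missing="raise").fit([[1, np.nan]])

    def test_get_set_params_roundtrip(self):
        est = ParetoRanker().set_params(on_missing="raise")
        assert est.get_params() == {"on_missing": "raise"}

    def test_works_in_sklearn_clone(self):
        from sklearn.base import clone

        est = clone(ParetoRanker(on_missing="raise"))
        assert est.on_missing == "raise"


class TestCompositeRank:
    def test_concordant_components(self):
        assert composite_pareto_rank_array([(1, 2, 3), (1, 2, 3)]).tolist() == [1, 2, 3]

    def test_discordant_components_all_front_one(self):
        assert composite_pareto_rank_array([(1, 3, 2), (3, 1, 2)]).tolist() == [1, 1, 1]

    def test_partial_tie(self):
        assert composite_pareto_rank_array([(1, 1), (1, 2)]).tolist() == [1, 2]

    def test_unranked_in_any_component_propagates(self):
        comp = composite_pareto_rank_array([(1, 0, 2), (1, 1, 2)])
        assert comp[1] == 0
        assert comp[[0, 2]].tolist() == [1, 2]

    def test_needs_two_components(self):
        with pytest.raises(ValueError, match="two components"):
            composite_pareto_rank_array([(1, 2)])

    def test_composite_widens_rank_range(self, rng):
        # two weakly related rankings: composite range >= each pooled component's
        a = pareto_rank_array(rng.random((200, 4)))
        b = pareto_rank_array(rng.random((200, 4)))
        comp = composite_pareto_rank_array([a, b])
        assert comp.max() >= 1
        assert set(np.unique(comp)) == set(range(1, comp.max() + 1))


class TestWeightedConsistency:
    def test_unit_weights(self, rng):
        X = rng.random((50, 3))
        assert check_weighted_consistency(X, np.ones(3))

    def test_extreme_weights_on_dominating_pair(self):
        X = np.array([[0.1, 0.1], [0.5, 0.9]])
        assert check_weighted_consistency(X, [0.1, 10.0])

    def test_random_instances(self, rng):
        for _ in range(5):
            X = rng.random((100, 4))
            w = rng.uniform(0.01, 10.0, size=4)
            assert check_weighted_consistency(X, w)

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            check_weighted_consistency(np.ones((2, 2)), [1.0, 0.0])


class TestRankAssignment:
    def test_contiguity_enforced(self):
        with pytest.raises(ValueError, match="contiguous"):
            RankAssignment(np.arange(3), np.array([1, 3, 3]))

    def test_unranked_marker_allowed(self):
        ra = RankAssignment(np.arange(4), np.array([1, 0, 2, 1]))
        assert ra.max_rank == 2
        assert ra.ranked_mask.tolist() == [True, False, True, True]

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            RankAssignment(np.array([1, 1]), np.array([1, 1]))
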