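"""Accumulation-layer KNN: distance, ranking, scoring, site selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eukloc.knn import (
    Neighbor,
    TrainingSet,
    al_scores,
    euclidean_distance,
    k_nearest,
    predict,
    predict_label_count,
    select_sites,
)
from oracles import al_scores_bruteforce, euclidean_bruteforce, knn_bruteforce


def make_model(vectors, labels, C=22, space="GO"):
    return TrainingSet(
        space=space,
        accessions=[f"T{i}" for i in range(len(vectors))],
        X=np.asarray(vectors, dtype=float),
        labels=[frozenset(l) for l in labels],
        C=C,
    )


class TestEuclideanDistance:
    def test_zero_iff_equal(self, rng):
        v = rng.normal(size=210)
        assert euclidean_distance(v, v) == 0.0

    def test_3_4_5_triangle(self):
        assert euclidean_distance(np.array([0.0, 0.0]), np.array([3.0, 4.0])) == 5.0

    def test_matches_bruteforce_on_210_dims(self, rng):
        for _ in range(10):
            u, v = rng.normal(size=(2, 210))
            assert euclidean_distance(u, v) == pytest.approx(
                euclidean_bruteforce(u, v), rel=1e-12
            )

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            euclidean_distance(np.zeros(3), np.zeros(4))


class TestKNearest:
    def test_k_equals_pool_returns_all_sorted(self):
        model = make_model([[0.0], [3.0], [1.0]], [{1}, {2}, {3}], C=3)
        nbrs = k_nearest(model, np.array([0.0]), K=3)
        assert [n.index for n in nbrs] == [0, 2, 1]
        assert [n.distance for n in nbrs] == [0.0, 1.0, 3.0]

    def test_tie_broken_by_training_order(self):
        model = make_model([[2.0], [-1.0], [1.0]], [{1}, {2}, {3}], C=3)
        nbrs = k_nearest(model, np.array([0.0]), K=2)
        # items 1 and 2 are both at distance 1: earlier index wins rank 1
        assert [n.index for n in nbrs] == [1, 2]

    def test_exclusion_removes_query(self):
        model = make_model([[0.0], [1.0]], [{1}, {2}], C=2)
        nbrs = k_nearest(model, np.array([0.0]), K=1, exclude="T0")
        assert [n.index for n in nbrs] == [1]

    def test_k_exceeding_pool_rejected(self):
        model = make_model([[0.0], [1.0]], [{1}, {2}], C=2)
        with pytest.raises(ValueError, match="exceeds"):
            k_nearest(model, np.array([0.0]), K=2, exclude="T0")

    def test_matches_full_enumeration(self, rng):
        X = rng.normal(size=(30, 5))
        model = make_model(X, [{1 + i % 5} for i in range(30)], C=5)
        q = rng.normal(size=5)
        got = k_nearest(model, q, K=7, exclude="T3")
        want = knn_bruteforce(X, q, K=7, exclude_idx=3)
        assert [(n.distance, n.index) for n in got] == pytest.approx(
            [(d, i) for d, i in want]
        )


class TestALScores:
    def test_single_neighbor_single_layer(self):
        model = make_model([[0.0]], [{7, 18}])
        scores = al_scores(model, [Neighbor(0, 0.5)])
        assert scores[6] == 1 and scores[17] == 1 and scores.sum() == 2

    def test_weight_rule_by_hand(self):
        # ranked label sets ({7}, {18}, {7}) with K=3: weights 3, 2, 1
        model = make_model([[0.0], [1.0], [2.0]], [{7}, {18}, {7}])
        scores = al_scores(model, [Neighbor(0, 0.1), Neighbor(1, 0.2), Neighbor(2, 0.3)])
        assert scores[6] == 4  # 3 + 1
        assert scores[17] == 2
        assert scores.sum() == 6

    @pytest.mark.parametrize("K", [1, 4, 10])
    def test_unanimous_site_scores_K_K_plus_1_over_2(self, K):
        model = make_model([[float(i)] for i in range(K)], [{5}] * K)
        nbrs = [Neighbor(i, float(i)) for i in range(K)]
        assert al_scores(model, nbrs)[4] == K * (K + 1) / 2

    def test_matches_layer_by_layer_bruteforce(self, rng):
        n, C, K = 25, 5, 9
        labels = [
            frozenset(rng.choice(C, size=rng.integers(1, 4), replace=False) + 1)
            for _ in range(n)
        ]
        model = make_model(rng.normal(size=(n, 3)), labels, C=C)
        nbrs = k_nearest(model, rng.normal(size=3), K=K)
        got = al_scores(model, nbrs)
        want = al_scores_bruteforce(model.labels, [n.index for n in nbrs], C)
        np.testing.assert_array_equal(got, want)

    def test_score_support_iff_neighbor_carries(self, rng):
        model = make_model(rng.normal(size=(6, 2)), [{1}, {2}, {2}, {3}, {1}, {4}], C=5)
        nbrs = k_nearest(model, rng.normal(size=2), K=4)
        scores = al_scores(model, nbrs)
        carried = set().union(*(model.labels[n.index] for n in nbrs))
        assert {c + 1 for c in np.flatnonzero(scores)} == carried


class TestLabelCount:
    def test_inherited_from_nearest(self):
        model = make_model([[0.0], [1.0]], [{3}, {1, 2, 5, 7}])
        assert predict_label_count(model, [Neighbor(0, 0.1), Neighbor(1, 0.9)]) == 1
        assert predict_label_count(model, [Neighbor(1, 0.1), Neighbor(0, 0.9)]) == 4

    def test_rank1_tie_uses_stable_winner(self):
        model = make_model([[1.0], [-1.0]], [{1, 2}, {3}])
        nbrs = k_nearest(model, np.array([0.0]), K=2)
        assert predict_label_count(model, nbrs) == 2  # index 0 wins the tie


class TestSelectSites:
    def test_unique_maximum(self):
        model = make_model([[0.0]], [{2}])
        scores = np.zeros(22)
        scores[1] = 5.0
        assert select_sites(scores, 1, [Neighbor(0, 0.1)], model) == {2}

    def test_top_three(self):
        model = make_model([[0.0]], [{1, 11, 22}])
        scores = np.zeros(22)
        scores[[0, 10, 21]] = [9.0, 8.0, 7.0]
        scores[4] = 1.0
        assert select_sites(scores, 3, [Neighbor(0, 0.1)], model) == {1, 11, 22}

    def test_tie_for_last_slot_goes_to_nearer_carrier(self):
        # sites 1 and 2 tie on score; site 2's nearest carrier is closer
        model = make_model([[0.0], [1.0], [2.0]], [{2}, {1}, {1}])
        nbrs = [Neighbor(0, 0.5), Neighbor(1, 1.0), Neighbor(2, 1.5)]
        scores = al_scores(model, nbrs)
        assert scores[0] == scores[1] == 3.0
        assert select_sites(scores, 1, nbrs, model) == {2}

    def test_equal_distance_tie_falls_back_to_smaller_code(self):
        model = make_model([[0.0]], [{4, 9}])
        nbrs = [Neighbor(0, 0.5)]
        scores = al_scores(model, nbrs)
        assert select_sites(scores, 1, nbrs, model) == {4}

    def test_m_out_of_range(self):
        model = make_model([[0.0]], [{1}], C=3)
        with pytest.raises(ValueError):
            select_sites(np.ones(3), 4, [Neighbor(0, 0.1)], model)


class TestPredict:
    def _models(self):
        go = make_model([[1.0, 0.0], [0.0, 1.0]], [{1}, {2}], C=3, space="GO")
        se = make_model([[5.0], [9.0]], [{1}, {2}], C=3, space="SeqEvo")
        return go, se

    def test_go_space_preferred_when_non_naught(self):
        go, se = self._models()
        pred = predict(go, se, "Q", np.array([0.9, 0.0]), np.array([9.0]), K=1)
        assert pred.space == "GO" and pred.labels == {1} and pred.status == "ok"

    def test_naught_go_falls_back_to_seqevo(self):
        go, se = self._models()
        pred = predict(go, se, "Q", np.zeros(2), np.array([9.0]), K=1)
        assert pred.space == "SeqEvo" and pred.labels == {2}

    def test_no_representation_abstains(self):
        go, se = self._models()
        pred = predict(go, se, "Q", np.zeros(2), None, K=1)
        assert pred.status == "abstained" and pred.labels == frozenset()


@st.composite
def random_training(draw):
    n = draw(st.integers(2, 15))
    dim = draw(st.integers(1, 4))
    C = 5
    X = [
        [draw(st.floats(-5, 5, allow_nan=False)) for _ in range(dim)]
        for _ in range(n)
    ]
    labels = [
        draw(st.sets(st.integers(1, C), min_size=1, max_size=3)) for _ in range(n)
    ]
    q = [draw(st.floats(-5, 5, allow_nan=False)) for _ in range(dim)]
    return X, labels, q


@settings(max_examples=60, derandomize=True, deadline=None)
@given(random_training())
def test_k1_reduces_to_nearest_neighbor_label_copy(case):
    """With K = 1 the prediction is exactly the nearest neighbor's label set."""
    X, labels, q = case
    model = make_model(X, labels, C=5)
    pred = predict(model, None, "Q", np.asarray(q), None, K=1)
    if pred.status == "abstained":  # naught query vector: no GO prediction
        assert not np.any(np.asarray(q))
        return
    nearest = k_nearest(model, np.asarray(q), K=1)[0]
    assert pred.labels == model.labels[nearest.index]
    assert pred.m == len(model.labels[nearest.index])


def test_self_prediction_returns_own_labels(rng):
    X = rng.normal(size=(10, 4))
    labels = [frozenset({1 + i % 4}) for i in range(10)]
    model = make_model(X, labels, C=4)
    for i in [0, 3, 7]:
        pred = predict(model, None, f"T{i}", X[i], None, K=1)
        assert pred.labels == labels[i]
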