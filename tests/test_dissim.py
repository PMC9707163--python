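"""Balanced sampling, AUC computation and dissimilarity matrix assembly."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stylemap.dissim import (
    DissimConfig,
    DissimilarityMatrix,
    PairSamplingPlan,
    auc_from_scores,
    auc_to_distance,
    balanced_sample_size,
    build_matrix,
    pair_dissimilarity,
    train_test_split_pair,
)
from stylemap.reference import GROUP_COMMENT_COUNTS


def brute_force_auc(scores, labels):
    """Exhaustive Mann-Whitney pair counting: concordant pairs plus half
    the ties, over all positive/negative pairs."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestBalancedSampleSize:
    @pytest.mark.parametrize(
        "n_a,n_b,total",
        [
            (GROUP_COMMENT_COUNTS["Entrepreneur"], GROUP_COMMENT_COUNTS["sales"], 50_512),
            (GROUP_COMMENT_COUNTS["asianamerican"], GROUP_COMMENT_COUNTS["islam"], 35_036),
            (GROUP_COMMENT_COUNTS["homeless"], GROUP_COMMENT_COUNTS["Teachers"], 15_496),
            (GROUP_COMMENT_COUNTS["Feminism"], GROUP_COMMENT_COUNTS["Conservative"], 30_772),
            (GROUP_COMMENT_COUNTS["Christianity"], GROUP_COMMENT_COUNTS["Libertarian"], 713_208),
            (GROUP_COMMENT_COUNTS["islam"], GROUP_COMMENT_COUNTS["islam"], 108_988),
        ],
    )
    def test_published_pairwise_totals(self, n_a, n_b, total):
        assert 2 * balanced_sample_size(n_a, n_b) == total

    def test_even_minimum_unchanged(self):
        assert balanced_sample_size(10, 10) == 10

    def test_odd_minimum_rounded_down(self):
        assert balanced_sample_size(17_519, 54_495) == 17_518

    def test_too_small_errors(self):
        with pytest.raises(ValueError):
            balanced_sample_size(1, 100)


class TestTrainTestSplitPair:
    def _plan(self, n, seed=0):
        return PairSamplingPlan(group_a="a", group_b="b", n_per_class=n, seed=seed)

    def test_fifty_fifty_balance(self):
        A = np.arange(300).reshape(150, 2).astype(float)
        B = -np.arange(400).reshape(200, 2).astype(float)
        Xtr, ytr, Xte, yte = train_test_split_pair(A, B, self._plan(100))
        assert Xtr.shape == Xte.shape == (100, 2)
        for y in (ytr, yte):
            assert (y == 0).sum() == (y == 1).sum() == 50

    def test_half_arithmetic(self):
        A = np.zeros((20_000, 1))
        B = np.ones((17_518, 1))
        Xtr, ytr, *_ = train_test_split_pair(A, B, self._plan(17_518))
        assert (ytr == 0).sum() == (ytr == 1).sum() == 8_759

    def test_same_seed_identical(self):
        rng = np.random.default_rng(7)
        A, B = rng.normal(size=(60, 3)), rng.normal(size=(80, 3))
        first = train_test_split_pair(A, B, self._plan(40, seed=11))
        second = train_test_split_pair(A, B, self._plan(40, seed=11))
        for x, y in zip(first, second):
            np.testing.assert_array_equal(x, y)

    def test_draw_without_replacement(self):
        A = np.arange(50, dtype=float).reshape(50, 1)
        B = A + 1000
        Xtr, ytr, Xte, yte = train_test_split_pair(A, B, self._plan(50))
        drawn_a = np.concatenate([Xtr[ytr == 0, 0], Xte[yte == 0, 0]])
        assert len(np.unique(drawn_a)) == 50

    def test_positive_class_is_lexicographically_larger(self):
        A = np.zeros((10, 1))
        B = np.ones((10, 1))
        # group_a="b" sorts after group_b="a": rows of A (labelled "b") are class 1
        plan = PairSamplingPlan(group_a="b", group_b="a", n_per_class=10, seed=0)
        _, ytr, Xte, yte = train_test_split_pair(A, B, plan)
        assert np.all(Xte[yte == 1] == 0.0)

    def test_plan_exceeding_availability(self):
        with pytest.raises(ValueError):
            train_test_split_pair(np.zeros((10, 1)), np.zeros((10, 1)), self._plan(12))

    def test_odd_plan_rejected(self):
        with pytest.raises(ValueError):
            self._plan(7)


class TestAucFromScores:
    def test_perfect_separation(self):
        assert auc_from_scores([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_ties_is_chance(self):
        assert auc_from_scores([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_hand_counted_example(self):
        # pairs (0.3,0.5)L (0.3,0.6)L (0.7,0.5)W (0.7,0.6)W -> 2/4
        assert auc_from_scores([0.3, 0.7, 0.5, 0.6], [1, 1, 0, 0]) == pytest.approx(0.5)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            auc_from_scores([0.1, 0.2], [1, 1])

    @settings(deadline=None, max_examples=200)
    @given(st.lists(st.integers(min_value=0, max_value=5), min_size=2, max_size=30)
           .map(lambda xs: [x / 5 for x in xs]),
           st.data())
    def test_matches_exhaustive_pair_counting(self, scores, data):
        n = len(scores)
        labels = data.draw(
            st.lists(st.integers(min_value=0, max_value=1), min_size=n, max_size=n)
            .filter(lambda ls: 0 < sum(ls) < n)
        )
        assert auc_from_scores(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels), abs=1e-12
        )


class TestPairDissimilarity:
    def test_split_half_of_one_corpus_is_chance(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(1200, 8))
        auc, plan = pair_dissimilarity(X[:600], X[600:], DissimConfig(seed=1, n_estimators=50),
                                       labels=("a", "b"))
        assert plan.n_per_class == 600
        assert abs(auc - 0.5) < 0.08

    def test_shifted_profile_separates(self):
        rng = np.random.default_rng(6)
        A = rng.normal(size=(400, 5))
        B = rng.normal(size=(400, 5))
        B[:, 0] += 3.0
        auc, _ = pair_dissimilarity(A, B, DissimConfig(seed=2, n_estimators=50))
        assert auc > 0.9

    def test_constant_features_warn_but_compute(self):
        A = np.zeros((40, 3))
        B = np.zeros((40, 3))
        with pytest.warns(UserWarning, match="constant"):
            auc, _ = pair_dissimilarity(A, B, DissimConfig(seed=3, n_estimators=10))
        assert 0.0 <= auc <= 1.0

    def test_max_per_class_caps_plan(self):
        rng = np.random.default_rng(8)
        A, B = rng.normal(size=(500, 3)), rng.normal(size=(700, 3))
        _, plan = pair_dissimilarity(
            A, B, DissimConfig(seed=0, n_estimators=10, max_per_class=100)
        )
        assert plan.n_per_class == 100


class TestBuildMatrix:
    def _groups(self, n_groups, n_rows=60, seed=0, shift=2.0):
        rng = np.random.default_rng(seed)
        return {
            f"g{i}": rng.normal(size=(n_rows, 4)) + shift * i for i in range(n_groups)
        }

    def test_pair_count_three_groups(self):
        D = build_matrix(self._groups(3), DissimConfig(seed=1, n_estimators=10))
        assert len(D.plans) == 3

    def test_symmetry_range_and_diagonal(self):
        D = build_matrix(self._groups(4), DissimConfig(seed=1, n_estimators=10))
        np.testing.assert_array_equal(D.values, D.values.T)
        assert np.all(np.diag(D.values) == 0.0)
        off = D.values[~np.eye(4, dtype=bool)]
        assert off.min() >= 0.0 and off.max() <= 1.0

    def test_half_diagonal_convention(self):
        D = build_matrix(self._groups(3),
                         DissimConfig(seed=1, n_estimators=10, diagonal="half"))
        assert np.all(np.diag(D.values) == 0.5)

    def test_order_invariance_up_to_permutation(self):
        groups = self._groups(4, seed=2)
        cfg = DissimConfig(seed=9, n_estimators=20)
        D1 = build_matrix(groups, cfg)
        reordered = {k: groups[k] for k in reversed(list(groups))}
        D2 = build_matrix(reordered, cfg)
        np.testing.assert_allclose(D2.reorder(D1.labels).values, D1.values)

    def test_fewer_than_three_groups_rejected(self):
        with pytest.raises(ValueError):
            build_matrix(self._groups(2), DissimConfig(n_estimators=10))

    def test_undersized_group_named_in_error(self):
        groups = self._groups(3)
        groups["tiny"] = np.zeros((1, 4))
        with pytest.raises(ValueError, match="tiny"):
            build_matrix(groups, DissimConfig(n_estimators=10))

    def test_asymmetric_matrix_rejected(self):
        vals = np.array([[0.0, 0.6, 0.7], [0.6, 0.0, 0.8], [0.9, 0.8, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            DissimilarityMatrix(labels=["a", "b", "c"], values=vals)


def test_auc_to_distance_maps_chance_to_zero():
    np.testing.assert_allclose(auc_to_distance(np.array([0.4, 0.5, 0.75, 1.0])),
                               [0.0, 0.0, 0.5, 1.0])


def test_null_calibration_small():
    """Same-profile pairs: mean AUC near 0.5 over seeded replicates."""
    rng = np.random.default_rng(123)
    aucs = []
    for rep in range(5):
        A = rng.normal(size=(300, 10))
        B = rng.normal(size=(300, 10))
        auc, _ = pair_dissimilarity(A, B, DissimConfig(seed=rep, n_estimators=40))
        aucs.append(auc)
    assert abs(np.mean(aucs) - 0.5) < 0.05
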