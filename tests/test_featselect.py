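"""Selector tests, including independently coded brute-force oracles.

The oracles below re-implement ReliefF, the information-gain entropy
arithmetic, and the greedy mRMR loop with explicit Python loops and no
shared code with the package, so agreement is a genuine two-route check.
"""

import math

import numpy as np
import pytest

from physprot import (
    FeatureMatrix,
    infogain_scores,
    mrmr_order,
    relieff_weights,
    top_k,
)
from physprot.featselect import _discretize_3state, mutual_information


def _matrix(X, y, ids=None):
    X = np.asarray(X, dtype=float)
    return FeatureMatrix(
        sample_ids=[f"s{i}" for i in range(X.shape[0])],
        feature_ids=ids or [f"f{j}" for j in range(X.shape[1])],
        X=X,
        y=np.asarray(y),
    )


# ---------------------------------------------------------------------------
# Brute-force oracles (independent implementations)


def brute_relieff(X, y, k):
    """ReliefF with explicit loops: range-normalized diffs, Manhattan
    distances, k nearest hits/misses (ties by index), every instance once."""
    n, d = X.shape
    rng_f = [max(X[:, f]) - min(X[:, f]) for f in range(d)]

    def diff(f, i, j):
        if rng_f[f] == 0:
            return 0.0
        return abs(X[i, f] - X[j, f]) / rng_f[f]

    def dist(i, j):
        return sum(diff(f, i, j) for f in range(d))

    priors = {c: float(np.mean(y == c)) for c in set(y.tolist())}
    W = [0.0] * d
    for i in range(n):
        hits = sorted(
            (j for j in range(n) if j != i and y[j] == y[i]),
            key=lambda j: (dist(i, j), j),
        )[:k]
        misses = sorted(
            (j for j in range(n) if y[j] != y[i]),
            key=lambda j: (dist(i, j), j),
        )[:k]
        w_prior = priors[y[misses[0]]] / (1.0 - priors[y[i]])
        for f in range(d):
            for h in hits:
                W[f] -= diff(f, i, h) / (n * k)
            for m_ in misses:
                W[f] += w_prior * diff(f, i, m_) / (n * k)
    return W


def brute_entropy(labels):
    out = 0.0
    for c in set(labels):
        p = labels.count(c) / len(labels)
        out -= p * math.log2(p)
    return out


def brute_mi(a, b):
    """Mutual information of two discrete sequences by direct tabulation."""
    n = len(a)
    mi = 0.0
    for av in set(a):
        for bv in set(b):
            pab = sum(1 for x, z in zip(a, b) if x == av and z == bv) / n
            if pab == 0:
                continue
            pa = a.count(av) / n
            pb = b.count(bv) / n
            mi += pab * math.log2(pab / (pa * pb))
    return mi


# ---------------------------------------------------------------------------
# ReliefF


class TestReliefF:
    def test_separating_feature_beats_constant(self, labeled_matrix):
        ranking = relieff_weights(labeled_matrix, k_neighbors=3)
        scores = dict(zip(ranking.feature_ids, ranking.scores))
        assert scores["sep"] > 0
        assert scores["const"] == 0.0
        assert ranking.feature_ids[0] == "sep"

    def test_duplicated_dataset_keeps_ranking_order(self, labeled_matrix):
        ranking = relieff_weights(labeled_matrix, k_neighbors=3)
        doubled = FeatureMatrix(
            sample_ids=labeled_matrix.sample_ids
            + [s + "_dup" for s in labeled_matrix.sample_ids],
            feature_ids=list(labeled_matrix.feature_ids),
            X=np.vstack([labeled_matrix.X, labeled_matrix.X]),
            y=np.concatenate([labeled_matrix.y, labeled_matrix.y]),
        )
        ranking2 = relieff_weights(doubled, k_neighbors=3)
        assert ranking2.feature_ids == ranking.feature_ids

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        X = rng.normal(size=(6, 3))
        y = np.array([-1, -1, -1, 1, 1, 1])
        m = _matrix(X, y)
        ranking = relieff_weights(m, k_neighbors=1)
        got = dict(zip(ranking.feature_ids, ranking.scores))
        expected = brute_relieff(X, y, k=1)
        for j in range(3):
            assert got[f"f{j}"] == pytest.approx(expected[j], abs=1e-12)

    def test_larger_fixture_matches_oracle(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(14, 5))
        y = np.array([-1] * 7 + [1] * 7)
        X[:7, 2] -= 1.5  # make one feature informative
        m = _matrix(X, y)
        ranking = relieff_weights(m, k_neighbors=3)
        got = dict(zip(ranking.feature_ids, ranking.scores))
        expected = brute_relieff(X, y, k=3)
        for j in range(5):
            assert got[f"f{j}"] == pytest.approx(expected[j], abs=1e-12)

    def test_single_class_rejected(self):
        m = _matrix(np.ones((4, 2)), [1, 1, 1, 1])
        with pytest.raises(ValueError):
            relieff_weights(m, k_neighbors=1)

    def test_k_too_large_rejected(self, labeled_matrix):
        with pytest.raises(ValueError):
            relieff_weights(labeled_matrix, k_neighbors=10)

    def test_row_order_invariance(self, labeled_matrix):
        ranking = relieff_weights(labeled_matrix, k_neighbors=3)
        perm = np.random.default_rng(0).permutation(labeled_matrix.n_samples)
        shuffled = FeatureMatrix(
            sample_ids=[labeled_matrix.sample_ids[i] for i in perm],
            feature_ids=list(labeled_matrix.feature_ids),
            X=labeled_matrix.X[perm],
            y=labeled_matrix.y[perm],
        )
        ranking2 = relieff_weights(shuffled, k_neighbors=3)
        assert ranking2.feature_ids == ranking.feature_ids
        assert ranking2.scores == pytest.approx(ranking.scores, abs=1e-12)


# ---------------------------------------------------------------------------
# Information gain


class TestInfoGain:
    def test_perfect_predictor_of_balanced_class_scores_one_bit(self):
        X = np.array([[0.0], [0.0], [0.0], [0.0], [1.0], [1.0], [1.0], [1.0]])
        y = np.array([-1, -1, -1, -1, 1, 1, 1, 1])
        ranking = infogain_scores(_matrix(X, y))
        assert ranking.scores[0] == pytest.approx(1.0, abs=1e-12)

    def test_class_independent_feature_scores_zero(self):
        X = np.array([[v] for v in [1.0, 2.0, 3.0, 4.0, 1.0, 2.0, 3.0, 4.0]])
        y = np.array([-1, -1, -1, -1, 1, 1, 1, 1])
        ranking = infogain_scores(_matrix(X, y))
        assert ranking.scores[0] == 0.0

    def test_matches_hand_entropy_arithmetic(self):
        # 12 instances, two distinct values => one candidate cut at 1.5:
        # left bin pure (6 neg), right bin 5 pos + 1 neg
        X = np.array([[1.0]] * 6 + [[2.0]] * 6)
        y = np.array([-1] * 6 + [1, 1, 1, 1, 1, -1])
        ranking = infogain_scores(_matrix(X, y))
        h_y = brute_entropy(list(y))
        h_right = brute_entropy([1, 1, 1, 1, 1, -1])
        expected = h_y - (0.5 * 0.0 + 0.5 * h_right)
        assert ranking.scores[0] == pytest.approx(expected, abs=1e-12)

    def test_mdl_refuses_weak_splits(self):
        # a split of marginal purity at n=8 fails the MDL acceptance bound
        X = np.array([[1.0]] * 4 + [[2.0]] * 4)
        y = np.array([-1, -1, -1, 1, 1, 1, 1, -1])
        ranking = infogain_scores(_matrix(X, y))
        assert ranking.scores[0] == 0.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            infogain_scores(_matrix(np.ones((4, 1)), [1, 1, 1, 1]))

    def test_scores_nonnegative_on_random_data(self):
        rng = np.random.default_rng(1)
        m = _matrix(rng.normal(size=(30, 6)), [-1] * 15 + [1] * 15)
        assert min(infogain_scores(m).scores) >= 0.0


# ---------------------------------------------------------------------------
# mRMR


class TestMrmr:
    @pytest.fixture
    def fixture20x5(self):
        rng = np.random.default_rng(9)
        y = np.array([-1] * 10 + [1] * 10)
        X = rng.normal(size=(20, 5))
        X[:, 0] += 2.0 * (y == 1)          # strongly relevant
        X[:, 1] = X[:, 0] + rng.normal(scale=0.1, size=20)  # redundant copy
        X[:, 3] += 1.0 * (y == 1)          # moderately relevant
        return _matrix(X, y)

    def test_first_pick_maximizes_mutual_information(self, fixture20x5):
        ranking = mrmr_order(fixture20x5, n_select=1)
        S = _discretize_3state(fixture20x5.X)
        yd = (fixture20x5.y > 0).astype(int)
        mis = [mutual_information(S[:, j], yd) for j in range(5)]
        assert ranking.feature_ids[0] == f"f{int(np.argmax(mis))}"

    def test_full_selection_is_a_permutation(self, fixture20x5):
        ranking = mrmr_order(fixture20x5, n_select=5)
        assert sorted(ranking.feature_ids) == [f"f{j}" for j in range(5)]

    def test_matches_brute_force_greedy_oracle(self, fixture20x5):
        S = _discretize_3state(fixture20x5.X)
        cols = [S[:, j].tolist() for j in range(5)]
        yd = [int(v > 0) for v in fixture20x5.y]
        relevance = [brute_mi(c, yd) for c in cols]
        selected, remaining = [], list(range(5))
        for step in range(3):
            best, best_crit = None, -math.inf
            for j in remaining:
                red = sum(brute_mi(cols[j], cols[s]) for s in selected)
                crit = relevance[j] - (red / step if step else 0.0)
                if crit > best_crit + 1e-15:
                    best, best_crit = j, crit
            selected.append(best)
            remaining.remove(best)
        ranking = mrmr_order(fixture20x5, n_select=3)
        assert list(ranking.feature_ids) == [f"f{j}" for j in selected]

    def test_n_select_out_of_range(self, fixture20x5):
        with pytest.raises(ValueError):
            mrmr_order(fixture20x5, n_select=6)

    def test_mi_bounded_by_entropies(self, fixture20x5):
        S = _discretize_3state(fixture20x5.X)
        yd = (fixture20x5.y > 0).astype(int)
        from physprot.featselect import _entropy

        for j in range(5):
            mi = mutual_information(S[:, j], yd)
            assert -1e-12 <= mi <= min(_entropy(S[:, j]), _entropy(yd)) + 1e-12


# ---------------------------------------------------------------------------
# top_k and cross-method properties


class TestTopK:
    def test_full_ranking_identity(self, labeled_matrix):
        ranking = relieff_weights(labeled_matrix, k_neighbors=3)
        assert top_k(ranking, 3) == list(ranking.feature_ids)

    def test_k1_is_argmax(self, labeled_matrix):
        ranking = relieff_weights(labeled_matrix, k_neighbors=3)
        assert top_k(ranking, 1) == ["sep"]

    def test_ties_break_to_lower_original_index(self):
        # two identical features tie on every score
        X = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0], [1.0, 1.0],
                      [0.0, 0.0], [1.0, 1.0]])
        y = np.array([-1, -1, 1, 1, -1, 1])
        ranking = infogain_scores(_matrix(X, y, ids=["first", "second"]))
        assert ranking.feature_ids == ("first", "second")

    def test_k_out_of_range(self, labeled_matrix):
        ranking = relieff_weights(labeled_matrix, k_neighbors=3)
        with pytest.raises(ValueError):
            top_k(ranking, 4)
        with pytest.raises(ValueError):
            top_k(ranking, 0)


def test_perfect_separator_ranks_first_under_all_methods():
    rng = np.random.default_rng(6)
    n = 30
    y = np.array([-1] * n + [1] * n)
    X = rng.normal(size=(2 * n, 4))
    X[:, 2] = y * 3.0 + rng.normal(scale=0.1, size=2 * n)  # clean separator
    m = _matrix(X, y)
    assert relieff_weights(m, k_neighbors=5).feature_ids[0] == "f2"
    assert infogain_scores(m).feature_ids[0] == "f2"
    assert mrmr_order(m, n_select=4).feature_ids[0] == "f2"
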