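import numpy as np
import pytest

from pespyramid import (
    RankedFeatures,
    ReliefFParams,
    SyntheticFeatureSpec,
    diff,
    generate_feature_matrix,
    iterative_select,
    make_svm_evaluator,
    minmax_normalize,
    relieff_rank,
)


def brute_force_relieff(X, y, k):
    """Independent reference: explicit pairwise distances, pure-python loops.

    One cycle per instance (m = n), Manhattan neighbor distance, ties broken
    by lower instance index, prior-weighted miss terms.
    """
    n, d = X.shape
    classes = sorted(set(y))
    priors = {c: sum(1 for t in y if t == c) / n for c in classes}
    w = [0.0] * d
    m = n
    for i in range(n):
        ci = y[i]
        for c in classes:
            cand = [j for j in range(n) if y[j] == c and j != i]
            cand.sort(key=lambda j: (sum(abs(X[i, a] - X[j, a]) for a in range(d)), j))
            kk = min(k, len(cand))
            if kk == 0:
                continue
            for a in range(d):
                s = sum(abs(X[i, a] - X[j, a]) for j in cand[:kk]) / (m * kk)
                if c == ci:
                    w[a] -= s
                else:
                    w[a] += priors[c] / (1.0 - priors[ci]) * s
    return np.asarray(w)


def random_problem(seed, n_max=30, d_max=8):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(8, n_max + 1))
    d = int(rng.integers(2, d_max + 1))
    X = minmax_normalize(rng.normal(size=(n, d)))
    y = rng.permutation(np.array(["a"] * (n // 2) + ["b"] * (n - n // 2)))
    return X, y


class TestMinMaxNormalize:
    def test_linear_map(self):
        out = minmax_normalize(np.array([[2.0], [4.0], [6.0]]))
        assert np.allclose(out.ravel(), [0.0, 0.5, 1.0])

    def test_constant_column_to_zero(self):
        out = minmax_normalize(np.array([[5.0, 1.0], [5.0, 2.0], [5.0, 3.0]]))
        assert np.all(out[:, 0] == 0.0)

    def test_idempotent_on_unit_range(self):
        col = np.array([[0.0], [0.25], [1.0]])
        assert np.allclose(minmax_normalize(col), col)

    def test_missing_values_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            minmax_normalize(np.array([[1.0], [np.nan]]))


class TestDiff:
    @pytest.mark.parametrize(
        "a,b,mode,expected",
        [
            (0.3, 0.3, "continuous", 0.0),
            (0.2, 0.9, "continuous", pytest.approx(0.7)),
            (0.3, 0.3, "discrete", 0.0),
            (0.2, 0.9, "discrete", 1.0),
        ],
    )
    def test_both_modes(self, a, b, mode, expected):
        assert diff(a, b, mode) == expected


class TestReliefFRank:
    def test_matches_bruteforce_on_toy(self):
        X, y = random_problem(seed=0, n_max=12, d_max=4)
        ranked = relieff_rank(X, y, ReliefFParams(k_neighbors=1))
        expected = brute_force_relieff(X, y, k=1)
        assert np.allclose(ranked.weights, expected, atol=1e-12)

    def test_class_indicator_feature_weight_is_one(self):
        # a perfect 0/1 class encoding with balanced classes: every hit diff
        # is 0 and every miss diff is 1, so the prior-weighted update sums to 1
        y = np.array(["a", "a", "a", "b", "b", "b"])
        X = (y == "b").astype(float).reshape(-1, 1)
        ranked = relieff_rank(X, y, ReliefFParams(k_neighbors=1))
        assert ranked.weights[0] == pytest.approx(1.0, abs=1e-12)

    def test_constant_feature_weight_zero_and_ranked_last(self):
        rng = np.random.default_rng(3)
        X = minmax_normalize(np.column_stack([rng.normal(size=20), np.full(20, 7.0)]))
        y = np.array(["a", "b"] * 10)
        ranked = relieff_rank(X, y, ReliefFParams(k_neighbors=2))
        assert ranked.weights[1] == 0.0

    def test_weights_bounded_on_unit_data(self):
        X, y = random_problem(seed=5)
        ranked = relieff_rank(X, y, ReliefFParams(k_neighbors=3))
        assert np.all(ranked.weights >= -1.0) and np.all(ranked.weights <= 1.0)

    def test_order_sorts_weights_descending(self):
        X, y = random_problem(seed=6)
        ranked = relieff_rank(X, y, ReliefFParams(k_neighbors=3))
        assert np.all(np.diff(ranked.weights[ranked.order]) <= 0)

    def test_permutation_invariance_with_distinct_distances(self):
        X, y = random_problem(seed=7, n_max=20, d_max=5)
        rng = np.random.default_rng(1)
        perm = rng.permutation(len(y))
        w0 = relieff_rank(X, y, ReliefFParams(k_neighbors=2)).weights
        w1 = relieff_rank(X[perm], y[perm], ReliefFParams(k_neighbors=2)).weights
        assert np.allclose(w0, w1, atol=1e-10)

    def test_k_clipping_warns(self):
        X, y = random_problem(seed=8, n_max=10, d_max=3)
        with pytest.warns(UserWarning, match="clipping"):
            relieff_rank(X, y, ReliefFParams(k_neighbors=50))

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).random((6, 3))
        with pytest.raises(ValueError, match="2 classes"):
            relieff_rank(X, np.array(["a"] * 6))

    def test_priors_are_empirical_frequencies(self):
        y = np.array(["a"] * 6 + ["b"] * 2)
        X = minmax_normalize(np.random.default_rng(2).random((8, 3)))
        ranked = relieff_rank(X, y, ReliefFParams(k_neighbors=1))
        assert ranked.priors == {"a": 0.75, "b": 0.25}

    def test_separation_monotonicity(self):
        # median weight of the informative block never decreases with delta
        medians = []
        for delta in (0.5, 1.0, 2.0, 3.0):
            weights = []
            for seed in range(7):
                fm, informative = generate_feature_matrix(
                    SyntheticFeatureSpec(n_per_class=40, n_features=10,
                                         n_informative=1, delta=delta, seed=seed)
                )
                ranked = relieff_rank(minmax_normalize(fm.values), fm.labels,
                                      ReliefFParams(k_neighbors=5))
                weights.append(ranked.weights[informative[0]])
            medians.append(np.median(weights))
        assert np.all(np.diff(medians) >= 0)


class TestIterativeSelect:
    def test_curve_matches_direct_reevaluation(self):
        rng = np.random.default_rng(9)
        X = rng.random((30, 3))
        y = np.array(["a", "b"] * 15)

        def evaluator(Xs, ys):  # deterministic toy loss
            return float(np.abs(np.corrcoef(Xs.mean(axis=1), ys == "a")[0, 1]))

        ranked = relieff_rank(minmax_normalize(X), y, ReliefFParams(k_neighbors=2))
        result = iterative_select(X, y, ranked, evaluator, step=1)
        expected = [evaluator(X[:, ranked.order[:i]], y) for i in (1, 2, 3)]
        assert np.allclose(result.losses, expected)
        assert result.best_size == int(np.argmin(expected)) + 1

    def test_separating_feature_selected_alone(self):
        rng = np.random.default_rng(10)
        n = 40
        y = np.array(["a"] * (n // 2) + ["b"] * (n // 2))
        X = rng.normal(size=(n, 5))
        X[:, 2] = np.where(y == "a", -1.0, 1.0)  # wide-margin separator
        ranked = relieff_rank(minmax_normalize(X), y, ReliefFParams(k_neighbors=5))
        assert ranked.order[0] == 2
        result = iterative_select(X, y, ranked, make_svm_evaluator(seed=0), step=1)
        assert result.losses[0] == 0.0 and result.best_size == 1
        assert list(result.selected_columns) == [2]

    def test_tie_breaks_to_smallest_prefix(self):
        X = np.random.default_rng(1).random((10, 4))
        y = np.array(["a", "b"] * 5)
        ranked = RankedFeatures(weights=np.zeros(4), order=np.arange(4), priors={})
        result = iterative_select(X, y, ranked, lambda Xs, ys: 0.25, step=1)
        assert result.best_size == 1

    def test_step_and_max_prefix_grid(self):
        X = np.random.default_rng(2).random((10, 9))
        y = np.array(["a", "b"] * 5)
        ranked = RankedFeatures(weights=np.zeros(9), order=np.arange(9), priors={})
        result = iterative_select(X, y, ranked, lambda Xs, ys: Xs.shape[1] / 10, step=3)
        assert list(result.prefix_sizes) == [3, 6, 9]

    def test_max_prefix_clipped_with_warning(self):
        X = np.random.default_rng(3).random((10, 4))
        y = np.array(["a", "b"] * 5)
        ranked = RankedFeatures(weights=np.zeros(4), order=np.arange(4), priors={})
        with pytest.warns(UserWarning, match="clipping"):
            result = iterative_select(X, y, ranked, lambda Xs, ys: 0.0,
                                      max_prefix=99, step=1)
        assert result.prefix_sizes[-1] == 4

    def test_mismatched_ranking_rejected(self):
        X = np.random.default_rng(4).random((10, 4))
        y = np.array(["a", "b"] * 5)
        ranked = RankedFeatures(weights=np.zeros(3), order=np.arange(3), priors={})
        with pytest.raises(ValueError, match="covers"):
            iterative_select(X, y, ranked, lambda Xs, ys: 0.0)
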