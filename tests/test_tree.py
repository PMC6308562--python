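import numpy as np
import pytest

from ferwrf import (
    ContractError,
    DecisionTree,
    SplitFunction,
    TreeParams,
    between_class_variance,
    grow_tree,
    information_gain,
    node_similarity,
    predict_distribution,
    sample_candidate_splits,
)
from ferwrf.tree import TreeNode, evaluate_candidate_gains


# ---------------------------------------------------------------------------
# Independent brute-force oracle: naive loops, no shared code with ferwrf.tree
# ---------------------------------------------------------------------------

def oracle_bcv(X, y, f):
    vals = [row[f] for row in X]
    mu = sum(vals) / len(vals)
    classes = sorted(set(y))
    total = 0.0
    for c in classes:
        cvals = [v for v, lab in zip(vals, y) if lab == c]
        mu_c = sum(cvals) / len(cvals)
        total += (len(cvals) / len(vals)) * (mu - mu_c) ** 2
    return total


def oracle_similarity(X, y):
    return sum(oracle_bcv(X, y, f) for f in range(len(X[0])))


def oracle_gain(X, y, left_rows, right_rows):
    n = len(left_rows) + len(right_rows)
    gain = oracle_similarity(X, y)
    for rows in (left_rows, right_rows):
        if rows:
            sub_X = [X[i] for i in rows]
            sub_y = [y[i] for i in rows]
            gain -= (len(rows) / n) * oracle_similarity(sub_X, sub_y)
    return gain


def random_subset(rng, n_max=30, d_max=5, c_max=4):
    n = int(rng.integers(2, n_max))
    d = int(rng.integers(1, d_max))
    X = rng.normal(0, 3, size=(n, d))
    y = rng.integers(0, int(rng.integers(2, c_max + 1)), size=n)
    return X, y


class TestSplitStatistics:
    def test_hand_example(self):
        """Class means 1 and 5, grand mean 3: between-class variance 4; the
        class-perfect split has gain exactly 4."""
        X = np.array([[0.0], [2.0], [4.0], [6.0]])
        y = np.array([0, 0, 1, 1])
        assert between_class_variance(X, y, 0) == pytest.approx(4.0, abs=1e-12)
        assert node_similarity(X, y) == pytest.approx(4.0, abs=1e-12)
        assert information_gain(X, y, [0, 1, 2, 3], [0, 1], [2, 3]) == pytest.approx(
            4.0, abs=1e-12
        )

    def test_single_class_subset_has_zero_variance(self, rng):
        X = rng.normal(size=(10, 3))
        y = np.zeros(10, dtype=int)
        assert node_similarity(X, y) == 0.0

    def test_constant_values_have_zero_variance(self):
        X = np.full((6, 2), 3.7)
        y = np.array([0, 1, 2, 0, 1, 2])
        assert node_similarity(X, y) == pytest.approx(0.0, abs=1e-12)

    def test_one_dimension_reduces_to_bcv(self, rng):
        X = rng.normal(size=(12, 1))
        y = rng.integers(0, 3, 12)
        assert node_similarity(X, y) == pytest.approx(between_class_variance(X, y, 0))

    def test_matches_bruteforce_oracle_on_random_subsets(self, rng):
        """>= 200 random node subsets agree with the naive double-loop oracle
        to 1e-10, for both the similarity and the split gain."""
        for _ in range(200):
            X, y = random_subset(rng)
            assert node_similarity(X, y) == pytest.approx(
                oracle_similarity(X.tolist(), y.tolist()), abs=1e-10
            )
            rows = np.arange(len(y))
            mask = rng.random(len(y)) < rng.random()
            left, right = rows[mask], rows[~mask]
            if len(left) == 0 or len(right) == 0:
                continue
            assert information_gain(X, y, rows, left, right) == pytest.approx(
                oracle_gain(X.tolist(), y.tolist(), left.tolist(), right.tolist()),
                abs=1e-10,
            )

    def test_replicated_mixture_split_has_zero_gain(self):
        """A split whose children replicate the parent's per-class value
        distribution gains nothing."""
        X = np.array([[0.0], [2.0], [4.0], [0.0], [2.0], [4.0]])
        y = np.array([0, 1, 2, 0, 1, 2])
        gain = information_gain(X, y, np.arange(6), [0, 1, 2], [3, 4, 5])
        assert gain == pytest.approx(0.0, abs=1e-9)

    def test_bad_partition_is_a_contract_error(self):
        X = np.zeros((4, 1))
        y = np.array([0, 1, 0, 1])
        with pytest.raises(ContractError):
            information_gain(X, y, [0, 1, 2, 3], [0, 1], [1, 2])

    def test_fast_candidate_gains_match_reference(self, rng):
        """The vectorized per-candidate evaluation used during growth equals
        the reference information_gain for every candidate."""
        for _ in range(20):
            X, y = random_subset(rng, n_max=40, d_max=6, c_max=5)
            params = TreeParams(n_candidate_features=X.shape[1])
            cands = sample_candidate_splits(X, params, rng)
            if not cands:
                continue
            gains = evaluate_candidate_gains(X, y, cands, int(y.max()) + 1)
            rows = np.arange(len(y))
            for cand, g in zip(cands, gains):
                mask = X[:, cand.feature_index] <= cand.threshold
                ref = information_gain(X, y, rows, rows[mask], rows[~mask])
                assert g == pytest.approx(ref, abs=1e-9)


class TestCandidateSampling:
    def test_constant_features_yield_no_candidates(self, rng):
        X = np.ones((10, 4))
        assert sample_candidate_splits(X, TreeParams(), rng) == []

    def test_same_seed_same_candidates(self):
        X = np.random.default_rng(0).normal(size=(20, 10))
        c1 = sample_candidate_splits(X, TreeParams(), np.random.default_rng(5))
        c2 = sample_candidate_splits(X, TreeParams(), np.random.default_rng(5))
        assert c1 == c2

    def test_thresholds_strictly_inside_range(self, rng):
        for _ in range(100):
            X, _ = random_subset(rng, n_max=25, d_max=6)
            for cand in sample_candidate_splits(X, TreeParams(), rng):
                col = X[:, cand.feature_index]
                assert col.min() < cand.threshold < col.max()


class TestGrowth:
    def test_pure_subset_is_a_single_leaf(self, rng):
        X = rng.normal(size=(12, 3))
        y = np.full(12, 2)
        tree = grow_tree(X, y, classes=range(4), rng=rng)
        assert tree.root.is_leaf
        np.testing.assert_allclose(tree.root.distribution, [0, 0, 1, 0])

    def test_separable_1d_gets_pure_leaves(self, rng):
        X = np.concatenate([rng.uniform(0, 1, 20), rng.uniform(2, 3, 20)])[:, None]
        y = np.array([0] * 20 + [1] * 20)
        tree = grow_tree(X, y, classes=(0, 1), params=TreeParams(max_depth=1), rng=rng)
        assert not tree.root.is_leaf
        assert 1.0 < tree.root.split.threshold < 2.0
        np.testing.assert_allclose(tree.root.left.distribution, [1, 0])
        np.testing.assert_allclose(tree.root.right.distribution, [0, 1])

    def test_depth_limit_and_leaf_count_conservation(self, rng):
        X = rng.normal(size=(200, 5))
        y = rng.integers(0, 6, 200)
        params = TreeParams(max_depth=4, min_samples_split=5)
        tree = grow_tree(X, y, classes=range(6), params=params, rng=rng)

        def check(node, depth):
            assert depth <= params.max_depth
            if node.is_leaf:
                return node.counts.sum()
            return check(node.left, depth + 1) + check(node.right, depth + 1)

        assert check(tree.root, 0) == 200

    def test_degenerate_mixed_node_becomes_frequency_leaf(self, rng):
        X = np.ones((9, 2))
        y = np.array([0, 0, 0, 1, 1, 1, 2, 2, 2])
        tree = grow_tree(X, y, classes=range(3), rng=rng)
        assert tree.root.is_leaf
        np.testing.assert_allclose(tree.root.distribution, [1 / 3, 1 / 3, 1 / 3])

    def test_entropy_criterion_matches_sklearn_predictions(self, rng):
        """With criterion=entropy the engine reproduces a standard
        information-gain tree's predictions on separable 2-D data."""
        sklearn_tree = pytest.importorskip("sklearn.tree")
        centers = np.array([[0, 0], [5, 0], [0, 5], [5, 5]])
        X = np.concatenate([c + rng.normal(0, 0.3, (25, 2)) for c in centers])
        y = np.repeat(np.arange(4), 25)
        params = TreeParams(criterion="entropy", n_candidate_features=2,
                            n_candidate_thresholds=25)
        ours = grow_tree(X, y, classes=range(4), params=params, rng=rng)
        ref = sklearn_tree.DecisionTreeClassifier(criterion="entropy", random_state=0)
        ref.fit(X, y)
        probe = np.concatenate([c + rng.normal(0, 0.3, (10, 2)) for c in centers])
        ours_pred = [int(np.argmax(predict_distribution(ours, x))) for x in probe]
        assert ours_pred == list(ref.predict(probe))


class TestPrediction:
    @pytest.fixture()
    def fixture_tree(self):
        """Depth-2 hand-built tree: x0 <= 1 -> leaf A; else x1 <= 5 -> B / C."""
        leaf_a = TreeNode(counts=np.array([8.0, 2.0]))
        leaf_b = TreeNode(counts=np.array([1.0, 3.0]))
        leaf_c = TreeNode(counts=np.array([5.0, 5.0]))
        inner = TreeNode(split=SplitFunction(1, 5.0), left=leaf_b, right=leaf_c)
        root = TreeNode(split=SplitFunction(0, 1.0), left=leaf_a, right=inner)
        return DecisionTree(root, n_features=2, classes=(0, 1))

    def test_single_leaf_tree_returns_leaf_distribution(self):
        tree = DecisionTree(TreeNode(counts=np.array([3.0, 1.0])), 5, (0, 1))
        np.testing.assert_allclose(predict_distribution(tree, np.zeros(5)), [0.75, 0.25])

    def test_hand_traced_paths(self, fixture_tree):
        np.testing.assert_allclose(
            predict_distribution(fixture_tree, np.array([0.5, 99.0])), [0.8, 0.2]
        )
        np.testing.assert_allclose(
            predict_distribution(fixture_tree, np.array([2.0, 4.0])), [0.25, 0.75]
        )
        np.testing.assert_allclose(
            predict_distribution(fixture_tree, np.array([2.0, 6.0])), [0.5, 0.5]
        )

    def test_boundary_routes_left(self, fixture_tree):
        np.testing.assert_allclose(
            predict_distribution(fixture_tree, np.array([1.0, 0.0])), [0.8, 0.2]
        )

    def test_dimension_mismatch_is_contract_error(self, fixture_tree):
        with pytest.raises(ContractError):
            predict_distribution(fixture_tree, np.zeros(3))

    def test_serialization_round_trip(self, rng):
        X = rng.normal(size=(60, 4))
        y = rng.integers(0, 3, 60)
        tree = grow_tree(X, y, classes=range(3), rng=rng)
        back = DecisionTree.from_dict(tree.to_dict(), 4, range(3), tree.params)
        for x in rng.normal(size=(20, 4)):
            np.testing.assert_allclose(
                predict_distribution(back, x), predict_distribution(tree, x)
            )
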