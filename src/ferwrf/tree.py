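"""Binary decision trees grown with a data-similarity (between-class
variance) split criterion.

A node holding samples with feature matrix X (N x D) and class labels y is
scored by its *data similarity*

    S = sum_f sum_c (n_c / N) * (mu_f - mu_cf)^2

the sum over feature dimensions of the between-class variance, where mu_f is
the node mean of dimension f and mu_cf the class-c mean.  A candidate split
into left/right children is scored by the gain

    dG = S_parent - (N_L / N) * S_left - (N_R / N) * S_right

and growth selects, among randomly sampled (dimension, threshold) candidates,
the split with maximal gain.  S is zero exactly when every class present in
the node shares the node mean in every dimension; in particular pure nodes
and nodes whose classes are indistinguishable in feature space both stop
splitting, leaving a frequency leaf.  An ``entropy`` criterion is provided as
a switch so the two objectives can be compared on equal machinery.

Routing convention: a sample goes left when ``x[f] <= tau``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .exceptions import ContractError, FerError

#: Relative floor under which a best gain is treated as zero (stops growth).
GAIN_TOL = 1e-12


@dataclass(frozen=True)
class SplitFunction:
    """Axis-aligned test ``x[feature_index] <= threshold`` (true routes left)."""

    feature_index: int
    threshold: float


@dataclass
class TreeParams:
    """Growth hyper-parameters.

    ``n_candidate_features`` defaults to ceil(sqrt(D)) when None;
    ``n_candidate_thresholds`` thresholds are drawn uniformly inside each
    sampled dimension's (min, max) range at the node.
    """

    max_depth: int = 15
    min_samples_split: int = 2
    n_candidate_features: Optional[int] = None
    n_candidate_thresholds: int = 10
    criterion: str = "data_similarity"

    def __post_init__(self):
        if self.criterion not in ("data_similarity", "entropy"):
            raise FerError(f"unknown criterion {self.criterion!r}")
        for name in ("max_depth", "min_samples_split", "n_candidate_thresholds"):
            if getattr(self, name) < 1:
                raise FerError(f"{name} must be a positive integer")
        if self.n_candidate_features is not None and self.n_candidate_features < 1:
            raise FerError("n_candidate_features must be a positive integer")

    def resolved_n_features(self, n_dims: int) -> int:
        if self.n_candidate_features is not None:
            return min(self.n_candidate_features, n_dims)
        return min(int(np.ceil(np.sqrt(n_dims))), n_dims)

    def to_dict(self) -> dict:
        return {
            "max_depth": self.max_depth,
            "min_samples_split": self.min_samples_split,
            "n_candidate_features": self.n_candidate_features,
            "n_candidate_thresholds": self.n_candidate_thresholds,
            "criterion": self.criterion,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TreeParams":
        return cls(**d)


@dataclass
class TreeNode:
    """Internal node (split + children) or leaf (class counts/distribution)."""

    split: Optional[SplitFunction] = None
    left: Optional["TreeNode"] = None
    right: Optional["TreeNode"] = None
    counts: Optional[np.ndarray] = None

    @property
    def is_leaf(self) -> bool:
        return self.split is None

    @property
    def distribution(self) -> np.ndarray:
        return self.counts / self.counts.sum()


@dataclass
class DecisionTree:
    root: TreeNode
    n_features: int
    classes: tuple
    params: TreeParams = field(default_factory=TreeParams)

    def predict_distribution(self, x: np.ndarray) -> np.ndarray:
        return predict_distribution(self, x)

    def predict_index(self, x: np.ndarray) -> int:
        """Argmax class index; ties broken toward the lowest index."""
        return int(np.argmax(self.predict_distribution(x)))

    def leaf_depth(self, x: np.ndarray) -> int:
        """Number of split comparisons on the root-to-leaf path for ``x``."""
        node, depth = self.root, 0
        while not node.is_leaf:
            node = node.left if x[node.split.feature_index] <= node.split.threshold else node.right
            depth += 1
        return depth

    def count_nodes(self) -> tuple[int, int]:
        """(internal nodes, leaves)."""
        internal = leaves = 0
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                leaves += 1
            else:
                internal += 1
                stack.extend((node.left, node.right))
        return internal, leaves

    def to_dict(self) -> dict:
        def enc(node: TreeNode) -> dict:
            if node.is_leaf:
                return {"counts": [int(c) for c in node.counts]}
            return {
                "f": node.split.feature_index,
                "tau": node.split.threshold,
                "left": enc(node.left),
                "right": enc(node.right),
            }

        return enc(self.root)

    @classmethod
    def from_dict(cls, d: dict, n_features: int, classes, params: TreeParams) -> "DecisionTree":
        def dec(nd: dict) -> TreeNode:
            if "counts" in nd:
                return TreeNode(counts=np.asarray(nd["counts"], dtype=float))
            return TreeNode(
                split=SplitFunction(int(nd["f"]), float(nd["tau"])),
                left=dec(nd["left"]),
                right=dec(nd["right"]),
            )

        return cls(dec(d), n_features, tuple(classes), params)


# ---------------------------------------------------------------------------
# Node statistics (reference implementations of the split objective)
# ---------------------------------------------------------------------------

def _as_subset(X: np.ndarray, y: np.ndarray):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim == 1:
        X = X[:, None]
    if len(X) != len(y):
        raise ContractError("X and y must have equal length")
    if len(y) == 0:
        raise FerError("empty node subset")
    return X, y

def between_class_variance(X: np.ndarray, y: np.ndarray, f: int) -> float:
    """Between-class variance of feature dimension ``f`` over a node subset:
    ``sum_c (n_c/N) * (mu_f - mu_cf)**2``."""
    X, y = _as_subset(X, y)
    vals = X[:, f]
    mu = vals.mean()
    total = 0.0
    for c in np.unique(y):
        vc = vals[y == c]
        total += (len(vc) / len(vals)) * (mu - vc.mean()) ** 2
    return float(total)

def node_similarity(X: np.ndarray, y: np.ndarray) -> float:
    """Data similarity of a node: between-class variance summed over all
    feature dimensions."""
    X, y = _as_subset(X, y)
    return float(sum(between_class_variance(X, y, f) for f in range(X.shape[1])))

def information_gain(
    X: np.ndarray,
    y: np.ndarray,
    parent: Sequence[int],
    left: Sequence[int],
    right: Sequence[int],
) -> float:
    """Data-similarity gain of a split of ``parent`` rows into ``left`` and
    ``right`` rows (indices into X/y).  The children must partition the
    parent; an empty child contributes zero."""
    parent = np.asarray(parent, dtype=np.intp)
    left = np.asarray(left, dtype=np.intp)
    right = np.asarray(right, dtype=np.intp)
    if len(left) + len(right) != len(parent) or not np.array_equal(
        np.sort(np.concatenate([left, right])), np.sort(parent)
    ):
        raise ContractError("left/right must be a disjoint partition of parent")
    n = len(parent)
    s_parent = node_similarity(X[parent], y[parent])
    gain = s_parent
    for child in (left, right):
        if len(child):
            gain -= (len(child) / n) * node_similarity(X[child], y[child])
    return float(gain)


# ---------------------------------------------------------------------------
# Candidate sampling and fast vectorized split search
# ---------------------------------------------------------------------------

def sample_candidate_splits(
    X: np.ndarray, params: TreeParams, rng: np.random.Generator
) -> list[SplitFunction]:
    """Draw candidate splits for a node: ``n_candidate_features`` dimensions
    sampled without replacement; per dimension, ``n_candidate_thresholds``
    thresholds drawn uniformly strictly inside that dimension's (min, max)
    range at the node.  Constant dimensions yield no thresholds.
    Deterministic given the generator state."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ContractError("X must be 2-D")
    n_dims = X.shape[1]
    dims = rng.choice(n_dims, size=params.resolved_n_features(n_dims), replace=False)
    out: list[SplitFunction] = []
    for d in dims:
        lo = X[:, d].min()
        hi = X[:, d].max()
        if not hi > lo:
            continue
        thr = rng.uniform(lo, hi, size=params.n_candidate_thresholds)
        for t in thr:
            if lo < t < hi:
                out.append(SplitFunction(int(d), float(t)))
    return out

def _similarity_from_sums(class_sums, class_counts, n):
    """S from per-class sum vectors, via
    S = (1/n) sum_c |s_c|^2 / n_c - |s|^2 / n^2  (empty classes contribute 0).

    ``class_sums``: (C, D, K) candidate-stacked sums; ``class_counts``: (C, K);
    ``n``: (K,).  Returns (K,).  Positions with n == 0 return 0.
    """
    sq = np.einsum("cdk,cdk->ck", class_sums, class_sums)
    safe_counts = np.where(class_counts > 0, class_counts, 1.0)
    per_class = np.where(class_counts > 0, sq / safe_counts, 0.0).sum(axis=0)
    tot = class_sums.sum(axis=0)  # (D, K)
    tot_sq = np.einsum("dk,dk->k", tot, tot)
    safe_n = np.where(n > 0, n, 1.0)
    return np.where(n > 0, per_class / safe_n - tot_sq / safe_n**2, 0.0)

def _entropy_from_counts(class_counts, n):
    """Shannon entropy (bits) from (C, K) counts; empty nodes return 0."""
    safe_n = np.where(n > 0, n, 1.0)
    p = class_counts / safe_n
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where(p > 0, -p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    return h.sum(axis=0)

def evaluate_candidate_gains(
    X: np.ndarray,
    y: np.ndarray,
    candidates: Sequence[SplitFunction],
    n_classes: int,
    criterion: str = "data_similarity",
) -> np.ndarray:
    """Gain of every candidate split at a node, vectorized over candidates.

    For the data-similarity criterion this equals :func:`information_gain`
    applied to each candidate's partition (up to floating-point round-off).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=np.intp)
    n = len(y)
    if not candidates:
        return np.empty(0)
    dims = np.array([c.feature_index for c in candidates])
    taus = np.array([c.threshold for c in candidates])
    left_mask = X[:, dims] <= taus[None, :]  # (N, K)
    onehot = np.zeros((n, n_classes))
    onehot[np.arange(n), y] = 1.0
    left_counts = onehot.T @ left_mask  # (C, K)
    counts = onehot.sum(axis=0)  # (C,)
    n_left = left_counts.sum(axis=0)
    n_right = n - n_left
    if criterion == "entropy":
        right_counts = counts[:, None] - left_counts
        h_parent = _entropy_from_counts(counts[:, None], np.array([float(n)]))[0]
        h_left = _entropy_from_counts(left_counts, n_left)
        h_right = _entropy_from_counts(right_counts, n_right)
        return h_parent - (n_left / n) * h_left - (n_right / n) * h_right
    # per-class, per-candidate left sum vectors via one matmul per class
    left_sums = np.zeros((n_classes, X.shape[1], len(candidates)))
    class_sums = np.zeros((n_classes, X.shape[1]))
    for c in range(n_classes):
        rows = y == c
        if rows.any():
            left_sums[c] = X[rows].T @ left_mask[rows]
            class_sums[c] = X[rows].sum(axis=0)
    right_sums = class_sums[:, :, None] - left_sums
    right_counts = counts[:, None] - left_counts
    s_parent = _similarity_from_sums(
        class_sums[:, :, None], counts[:, None], np.array([float(n)])
    )[0]
    s_left = _similarity_from_sums(left_sums, left_counts, n_left)
    s_right = _similarity_from_sums(right_sums, right_counts, n_right)
    return s_parent - (n_left / n) * s_left - (n_right / n) * s_right


# ---------------------------------------------------------------------------
# Growth and prediction
# ---------------------------------------------------------------------------

def grow_tree(
    X: np.ndarray,
    y: np.ndarray,
    classes: Sequence,
    params: TreeParams | None = None,
    rng: np.random.Generator | None = None,
) -> DecisionTree:
    """Grow a tree top-down, at each node taking the sampled candidate with
    maximal gain (ties: first encountered under the seeded stream).  A node
    becomes a leaf when the depth limit is reached, it is pure or too small,
    no candidate exists, or the best gain is not positive."""
    params = params or TreeParams()
    rng = rng if rng is not None else np.random.default_rng()
    X, y = _as_subset(np.asarray(X, dtype=float), np.asarray(y, dtype=np.intp))
    n_classes = len(classes)
    if y.min() < 0 or y.max() >= n_classes:
        raise ContractError("labels must be indices into the class vocabulary")

    def build(rows: np.ndarray, depth: int) -> TreeNode:
        ys = y[rows]
        counts = np.bincount(ys, minlength=n_classes).astype(float)
        leaf = TreeNode(counts=counts)
        if (
            depth >= params.max_depth
            or len(rows) < params.min_samples_split
            or np.count_nonzero(counts) <= 1
        ):
            return leaf
        Xs = X[rows]
        candidates = sample_candidate_splits(Xs, params, rng)
        if not candidates:
            return leaf
        gains = evaluate_candidate_gains(Xs, ys, candidates, n_classes, params.criterion)
        best = int(np.argmax(gains))
        if not gains[best] > GAIN_TOL:
            return leaf
        split = candidates[best]
        mask = Xs[:, split.feature_index] <= split.threshold
        if not mask.any() or mask.all():  # cannot happen for interior thresholds
            return leaf
        return TreeNode(
            split=split,
            left=build(rows[mask], depth + 1),
            right=build(rows[~mask], depth + 1),
        )

    root = build(np.arange(len(y)), 0)
    return DecisionTree(root, X.shape[1], tuple(classes), replace(params))

def predict_distribution(tree: DecisionTree, x: np.ndarray) -> np.ndarray:
    """Route a feature vector to its leaf and return the leaf's class
    distribution (normalized frequencies)."""
    x = np.asarray(x, dtype=float)
    if x.shape != (tree.n_features,):
        raise ContractError(
            f"feature vector of length {x.shape} does not match tree D={tree.n_features}"
        )
    node = tree.root
    while not node.is_leaf:
        node = node.left if x[node.split.feature_index] <= node.split.threshold else node.right
    return node.distribution
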