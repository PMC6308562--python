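"""Weighted random forests with out-of-bag tree weighting and pruning.

Each tree is trained on an in-of-bag (IOB) bootstrap resample (N draws with
replacement from the N training samples) and scored on the out-of-bag (OOB)
samples it never saw.  A tree whose OOB accuracy falls below the pruning
threshold (default 0.5) is discarded; training repeats until the requested
number of surviving trees is reached.  Each survivor votes with weight equal
to its OOB accuracy, so the ensemble distribution is

    p(c | x) = sum_t w_t * p_t(c | x) / sum_t w_t

and the predicted class is the argmax (identical to the argmax of the
unnormalized weighted sum, since the normalizer is positive).  With
``weighting="uniform"`` all weights are 1 and the ensemble reduces to the
plain average vote of an ordinary random forest; pruning still applies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .exceptions import ContractError, FerError, TrainingFailureError
from .tree import DecisionTree, TreeParams, grow_tree

logger = logging.getLogger(__name__)


@dataclass
class ForestParams:
    """Training configuration for one weighted random forest.

    ``n_trees`` is the number of *surviving* trees the forest must contain
    (the ensemble size the vote divides by).  ``max_attempts`` caps the total
    number of trees built, survivors plus pruned; it defaults to
    ``10 * n_trees``.
    """

    n_trees: int = 200
    prune_threshold: float = 0.5
    max_attempts: Optional[int] = None
    tree_params: TreeParams = field(default_factory=TreeParams)
    weighting: str = "oob_weighted"

    def __post_init__(self):
        if self.n_trees < 1:
            raise FerError("n_trees must be >= 1")
        if not 0.0 <= self.prune_threshold < 1.0:
            raise FerError("prune_threshold must lie in [0, 1)")
        if self.weighting not in ("oob_weighted", "uniform"):
            raise FerError(f"unknown weighting {self.weighting!r}")
        if self.max_attempts is not None and self.max_attempts < self.n_trees:
            raise FerError("max_attempts must be >= n_trees")

    def resolved_max_attempts(self) -> int:
        return self.max_attempts if self.max_attempts is not None else 10 * self.n_trees

    def to_dict(self) -> dict:
        return {
            "n_trees": self.n_trees,
            "prune_threshold": self.prune_threshold,
            "max_attempts": self.max_attempts,
            "tree_params": self.tree_params.to_dict(),
            "weighting": self.weighting,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ForestParams":
        d = dict(d)
        d["tree_params"] = TreeParams.from_dict(d["tree_params"])
        return cls(**d)


@dataclass
class WeightedForest:
    trees: list[DecisionTree]
    weights: np.ndarray
    classes: tuple
    stream: str = ""
    params: ForestParams = field(default_factory=ForestParams)

    @property
    def n_features(self) -> int:
        return self.trees[0].n_features

    def to_dict(self) -> dict:
        return {
            "stream": self.stream,
            "classes": list(self.classes),
            "params": self.params.to_dict(),
            "weights": [float(w) for w in self.weights],
            "trees": [t.to_dict() for t in self.trees],
            "n_features": self.n_features,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "WeightedForest":
        params = ForestParams.from_dict(d["params"])
        classes = tuple(d["classes"])
        trees = [
            DecisionTree.from_dict(td, int(d["n_features"]), classes, params.tree_params)
            for td in d["trees"]
        ]
        return cls(trees, np.asarray(d["weights"], dtype=float), classes, d["stream"], params)


def bootstrap_indices(n: int, rng: np.random.Generator):
    """One bagging round: IOB row indices (n draws with replacement, in draw
    order) and the sorted OOB indices never drawn."""
    iob = rng.integers(0, n, size=n)
    mask = np.ones(n, dtype=bool)
    mask[iob] = False
    return iob, np.flatnonzero(mask)


def bootstrap_split(dataset, rng: np.random.Generator):
    """Dataset-level bagging: returns ``(iob, oob)`` as two datasets (the IOB
    a size-N multiset resample, the OOB the samples never drawn)."""
    if len(dataset) == 0:
        raise FerError("cannot bootstrap an empty dataset")
    iob, oob = bootstrap_indices(len(dataset), rng)
    return dataset.subset(iob), dataset.subset(oob)


def _tree_oob_accuracy(tree: DecisionTree, X: np.ndarray, y: np.ndarray) -> float:
    pred = np.fromiter((tree.predict_index(x) for x in X), dtype=np.intp, count=len(X))
    return float(np.mean(pred == y))


def train_wrf(
    X: np.ndarray,
    y: np.ndarray,
    classes: Sequence,
    params: ForestParams | None = None,
    rng: np.random.Generator | None = None,
    stream: str = "",
) -> WeightedForest:
    """Train a weighted random forest on a feature matrix.

    Repeats {bootstrap -> grow tree on IOB -> score on OOB}; trees with OOB
    accuracy below ``prune_threshold`` are discarded and leave no trace in
    predictions.  Raises :class:`TrainingFailureError` when ``max_attempts``
    trees have been built before ``n_trees`` survive.  A tree whose OOB set
    is empty (possible at tiny N) is accepted with the minimum admissible
    weight ``prune_threshold`` and a warning is logged.
    """
    params = params or ForestParams()
    rng = rng if rng is not None else np.random.default_rng()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=np.intp)
    if len(X) != len(y) or len(y) == 0:
        raise ContractError("X and y must be non-empty and of equal length")
    if len(np.unique(y)) < 2:
        raise FerError("training data must contain at least 2 classes")
    n = len(y)
    trees: list[DecisionTree] = []
    weights: list[float] = []
    attempts = 0
    max_attempts = params.resolved_max_attempts()
    while len(trees) < params.n_trees:
        if attempts >= max_attempts:
            raise TrainingFailureError(
                f"forest training exhausted {attempts} attempts with only "
                f"{len(trees)} / {params.n_trees} trees reaching OOB accuracy "
                f">= {params.prune_threshold}",
                attempts=attempts,
                survivors=len(trees),
            )
        attempts += 1
        iob, oob = bootstrap_indices(n, rng)
        tree = grow_tree(X[iob], y[iob], classes, params.tree_params, rng)
        if len(oob) == 0:
            logger.warning(
                "attempt %d: empty OOB set; accepting tree with weight %.3f",
                attempts, params.prune_threshold,
            )
            acc = params.prune_threshold
        else:
            acc = _tree_oob_accuracy(tree, X[oob], y[oob])
            if acc < params.prune_threshold:
                continue
        trees.append(tree)
        weights.append(1.0 if params.weighting == "uniform" else acc)
    logger.info(
        "trained %s forest: %d trees in %d attempts, mean weight %.3f",
        stream or "feature", len(trees), attempts, float(np.mean(weights)),
    )
    return WeightedForest(trees, np.asarray(weights, dtype=float), tuple(classes), stream, params)


def forest_distribution(forest: WeightedForest, x: np.ndarray) -> np.ndarray:
    """Weight-normalized ensemble class distribution
    ``sum_t w_t p_t(c|x) / sum_t w_t``."""
    x = np.asarray(x, dtype=float)
    if x.shape != (forest.n_features,):
        raise ContractError(
            f"feature vector shape {x.shape} does not match forest D={forest.n_features}"
        )
    acc = np.zeros(len(forest.classes))
    for tree, w in zip(forest.trees, forest.weights):
        acc += w * tree.predict_distribution(x)
    return acc / forest.weights.sum()


def classify(forest: WeightedForest, x: np.ndarray):
    """Weighted-vote label: argmax over classes of the weighted ensemble
    distribution; ties broken toward the lowest class index."""
    return forest.classes[int(np.argmax(forest_distribution(forest, x)))]
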