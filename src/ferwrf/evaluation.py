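"""Cross-validation protocols, confusion matrices and model-size accounting.

Two fold modes are supported: ``random`` (seeded shuffle, round-robin
assignment, fold sizes differing by at most one) and ``subject_independent``
(whole subjects assigned round-robin after a seeded shuffle, so no subject
contributes to both a training and a test fold — the person-independent
protocol).

Model size is reported as

* parameters: over all forests, 2 per internal node (feature index +
  threshold) plus one probability per leaf per class;
* operations: mean over a probe set of the number of split comparisons on
  the root-to-leaf paths of every tree, plus a fixed arithmetic constant per
  prediction for stream fusion (3 * C per stage: two scalings and one add)
  and, for the hierarchical model, one multiply per group member for the
  cross-level chaining.  The counting convention is ours; only its
  definition, not any particular printed value, is claimed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .exceptions import FerError, ProtocolError
from .features import FeatureConfig, default_config, extract_features_batch
from .forest import ForestParams
from .hierarchy import (
    FlatModel,
    FusionWeights,
    HierarchicalModel,
    train_hierarchical,
    train_single,
)
from .landmarks import EXPRESSIONS, Dataset


@dataclass
class FoldPlan:
    k: int
    mode: str
    fold_of: np.ndarray  # fold index per sample

    def fold_rows(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of == fold)


def make_folds(
    dataset: Dataset, k: int, mode: str = "random", rng: np.random.Generator | None = None
) -> FoldPlan:
    """Partition a dataset into k folds; deterministic given the generator."""
    rng = rng if rng is not None else np.random.default_rng()
    if k < 2:
        raise ProtocolError("k must be >= 2")
    n = len(dataset)
    fold_of = np.empty(n, dtype=np.intp)
    if mode == "random":
        if n < k:
            raise ProtocolError(f"cannot make {k} folds from {n} samples")
        order = rng.permutation(n)
        fold_of[order] = np.arange(n) % k
    elif mode == "subject_independent":
        subjects = np.asarray(sorted(set(dataset.subjects)), dtype=object)
        if len(subjects) < k:
            raise ProtocolError(
                f"subject-independent {k}-fold needs >= {k} distinct subjects, "
                f"got {len(subjects)}"
            )
        order = rng.permutation(len(subjects))
        fold_of_subject = {subjects[order[i]]: i % k for i in range(len(subjects))}
        fold_of[:] = [fold_of_subject[s] for s in dataset.subjects]
    else:
        raise ProtocolError(f"unknown fold mode {mode!r}")
    return FoldPlan(k, mode, fold_of)


@dataclass
class ModelSizeReport:
    n_parameters: int
    n_operations: float

    def to_dict(self) -> dict:
        return {
            "n_parameters": self.n_parameters,
            "n_parameters_millions": self.n_parameters / 1e6,
            "n_operations": self.n_operations,
            "n_operations_millions": self.n_operations / 1e6,
        }


def _model_pairs(model):
    if isinstance(model, HierarchicalModel):
        return [model.level1, model.level2]
    if isinstance(model, FlatModel):
        return [model.pair]
    raise FerError(f"unsupported model type {type(model).__name__}")


def count_model_size(model, probe: Dataset | np.ndarray) -> ModelSizeReport:
    """Parameter and mean per-prediction operation counts (see module doc)."""
    coords = probe.coords if isinstance(probe, Dataset) else np.asarray(probe)
    if len(coords) == 0:
        raise FerError("probe set must be non-empty")
    pairs = _model_pairs(model)
    n_params = 0
    for pair in pairs:
        for forest in (pair.distratio_forest, pair.anglerelat_forest):
            c = len(forest.classes)
            for tree in forest.trees:
                internal, leaves = tree.count_nodes()
                n_params += 2 * internal + c * leaves
    Xd, Xa = extract_features_batch(coords, model.config)
    total_ops = 0.0
    for i in range(len(coords)):
        ops = 0
        for pair in pairs:
            for forest, x in ((pair.distratio_forest, Xd[i]), (pair.anglerelat_forest, Xa[i])):
                ops += sum(t.leaf_depth(x) for t in forest.trees)
            ops += 3 * len(pair.classes)  # fusion arithmetic
        if isinstance(model, HierarchicalModel):
            ops += len(model.group)  # cross-level chaining multiplies
        total_ops += ops
    return ModelSizeReport(n_params, total_ops / len(coords))


@dataclass
class EvaluationReport:
    """Aggregated k-fold results over the 6-expression vocabulary."""

    kind: str
    k: int
    mode: str
    seed: Optional[int]
    per_fold_accuracy: list[float]
    confusion_counts: np.ndarray  # (6, 6); rows true, columns predicted
    model_size: ModelSizeReport
    params_echo: dict = field(default_factory=dict)

    @property
    def overall_accuracy(self) -> float:
        total = self.confusion_counts.sum()
        return float(np.trace(self.confusion_counts) / total)

    @property
    def confusion_percent(self) -> np.ndarray:
        rows = self.confusion_counts.sum(axis=1, keepdims=True)
        safe = np.where(rows > 0, rows, 1)
        return np.where(rows > 0, 100.0 * self.confusion_counts / safe, 0.0)

    def to_dict(self) -> dict:
        pct = self.confusion_percent
        return {
            "kind": self.kind,
            "k": self.k,
            "mode": self.mode,
            "seed": self.seed,
            "classes": list(EXPRESSIONS),
            "overall_accuracy": self.overall_accuracy,
            "overall_accuracy_percent": 100.0 * self.overall_accuracy,
            "overall_accuracy_rendered": f"{100.0 * self.overall_accuracy:.1f}",
            "per_fold_accuracy": [float(a) for a in self.per_fold_accuracy],
            "confusion_counts": [[int(v) for v in row] for row in self.confusion_counts],
            "confusion_percent": [[float(v) for v in row] for row in pct],
            "confusion_percent_rendered": [[f"{v:.1f}" for v in row] for row in pct],
            "model_size": self.model_size.to_dict(),
            "params": self.params_echo,
        }

    def to_json(self, indent: int = 1) -> str:
        return json.dumps(self.to_dict(), indent=indent)


def cross_validate(
    dataset: Dataset,
    kind: str = "hierarchical",
    params: ForestParams | None = None,
    fusion: FusionWeights | None = None,
    config: FeatureConfig | None = None,
    k: int = 5,
    mode: str = "random",
    seed: Optional[int] = None,
) -> EvaluationReport:
    """Train-and-test over a k-fold plan; pooled confusion matrix, per-fold
    accuracies and the mean model size across folds.

    Every training split must contain all six classes; a missing class is a
    protocol error naming the fold and class.
    """
    if kind not in ("hierarchical", "flat"):
        raise FerError(f"unknown model kind {kind!r}")
    params = params or ForestParams()
    fusion = fusion or FusionWeights()
    config = config or default_config()
    rng = np.random.default_rng(seed)
    plan = make_folds(dataset, k, mode, rng)
    confusion = np.zeros((len(EXPRESSIONS), len(EXPRESSIONS)), dtype=np.int64)
    per_fold = []
    size_params, size_ops = [], []
    for fold in range(k):
        test_rows = plan.fold_rows(fold)
        train_rows = np.flatnonzero(plan.fold_of != fold)
        train = dataset.subset(train_rows)
        test = dataset.subset(test_rows)
        present = set(train.labels)
        for cls in EXPRESSIONS:
            if cls not in present:
                raise ProtocolError(f"fold {fold}: class {cls!r} missing from training split")
        if kind == "hierarchical":
            model = train_hierarchical(train, params, fusion, config, rng, training_seed=seed)
        else:
            model = train_single(train, params, fusion, config, rng, training_seed=seed)
        pred, _ = model.predict_batch(test.coords)
        truth = test.label_indices()
        pred_idx = np.array([EXPRESSIONS.index(p) for p in pred], dtype=np.intp)
        per_fold.append(float(np.mean(pred_idx == truth)))
        np.add.at(confusion, (truth, pred_idx), 1)
        size = count_model_size(model, test)
        size_params.append(size.n_parameters)
        size_ops.append(size.n_operations)
    report = EvaluationReport(
        kind=kind,
        k=k,
        mode=mode,
        seed=seed,
        per_fold_accuracy=per_fold,
        confusion_counts=confusion,
        model_size=ModelSizeReport(
            int(round(float(np.mean(size_params)))), float(np.mean(size_ops))
        ),
        params_echo={
            "forest": params.to_dict(),
            "fusion": {"w1": fusion.w1, "w2": fusion.w2},
        },
    )
    return report
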