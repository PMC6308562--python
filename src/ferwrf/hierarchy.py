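"""Two-level coarse-to-fine expression classifier with dual-stream fusion.

Anger, disgust and sadness produce similar landmark geometry, so a flat
6-way classifier tends to confuse them.  The hierarchy first separates the
easy expressions (fear, happiness, surprise) from the confusable
anger/disgust/sadness group, then resolves that group with a dedicated
second-level classifier trained only on its members.

At each level two weighted random forests are trained separately, one per
feature stream (distance ratios and angle relations), and their class
distributions are fused by a convex combination

    p = w1 * p_distratio + w2 * p_anglerelat      (defaults w1=0.4, w2=0.6)

The final 6-class distribution chains the levels: easy classes keep their
level-1 fused probability, and each group member c gets
``q(group) * r(c)`` where q is the level-1 and r the level-2 fused
distribution.  This product rule is the unique combination that yields a
normalized 6-class distribution from the two stages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .exceptions import ContractError, FerError
from .features import FeatureConfig, default_config, extract_features_batch
from .forest import ForestParams, WeightedForest, forest_distribution, train_wrf
from .landmarks import EXPRESSIONS, Dataset

#: Synthetic level-1 label standing for the confusable group.
GROUP_LABEL = "group_ads"

#: Expressions resolved at level 2 by default.
DEFAULT_GROUP: tuple[str, ...] = ("anger", "disgust", "sadness")


@dataclass(frozen=True)
class FusionWeights:
    """Convex weights of the two feature streams (distance ratio, angle
    relation).  Must be non-negative and sum to 1."""

    w1: float = 0.4
    w2: float = 0.6

    def __post_init__(self):
        if self.w1 < 0 or self.w2 < 0:
            raise FerError("fusion weights must be non-negative")
        if abs(self.w1 + self.w2 - 1.0) > 1e-9:
            raise FerError(f"fusion weights must sum to 1, got {self.w1} + {self.w2}")


def fuse(p_dist: np.ndarray, p_angle: np.ndarray, fusion: FusionWeights) -> np.ndarray:
    """``w1 * p_dist + w2 * p_angle`` over a shared class vocabulary."""
    p_dist = np.asarray(p_dist, dtype=float)
    p_angle = np.asarray(p_angle, dtype=float)
    if p_dist.shape != p_angle.shape:
        raise ContractError("stream distributions are over different vocabularies")
    return fusion.w1 * p_dist + fusion.w2 * p_angle


@dataclass
class StreamPair:
    """One classification stage: a forest per feature stream plus fusion
    weights.  Both forests share one class vocabulary."""

    distratio_forest: WeightedForest
    anglerelat_forest: WeightedForest
    fusion: FusionWeights

    def __post_init__(self):
        if self.distratio_forest.classes != self.anglerelat_forest.classes:
            raise ContractError("stream forests must share one class vocabulary")

    @property
    def classes(self) -> tuple:
        return self.distratio_forest.classes

    def distribution(self, x_dist: np.ndarray, x_angle: np.ndarray) -> np.ndarray:
        return fuse(
            forest_distribution(self.distratio_forest, x_dist),
            forest_distribution(self.anglerelat_forest, x_angle),
            self.fusion,
        )

    def to_dict(self) -> dict:
        return {
            "fusion": {"w1": self.fusion.w1, "w2": self.fusion.w2},
            "distratio_forest": self.distratio_forest.to_dict(),
            "anglerelat_forest": self.anglerelat_forest.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StreamPair":
        return cls(
            WeightedForest.from_dict(d["distratio_forest"]),
            WeightedForest.from_dict(d["anglerelat_forest"]),
            FusionWeights(**d["fusion"]),
        )


def _train_pair(
    Xd: np.ndarray,
    Xa: np.ndarray,
    y: np.ndarray,
    classes: Sequence[str],
    params: ForestParams,
    fusion: FusionWeights,
    rng: np.random.Generator,
) -> StreamPair:
    # fixed draw order: distance-ratio forest first, then angle-relation
    fd = train_wrf(Xd, y, classes, params, rng, stream="distratio")
    fa = train_wrf(Xa, y, classes, params, rng, stream="anglerelat")
    return StreamPair(fd, fa, fusion)


@dataclass
class HierarchicalModel:
    """Level-1 (easy vs group) and level-2 (within-group) stream pairs."""

    level1: StreamPair
    level2: StreamPair
    config: FeatureConfig
    training_seed: Optional[int] = None
    group: tuple[str, ...] = DEFAULT_GROUP

    kind = "hierarchical"

    def __post_init__(self):
        if tuple(self.level2.classes) != tuple(self.group):
            raise ContractError("level-2 vocabulary must equal the confusable group")

    def predict(self, landmarks: np.ndarray):
        label, dist = self.predict_batch(np.asarray(landmarks)[None, :, :])
        return label[0], dist[0]

    def predict_batch(self, coords: np.ndarray):
        Xd, Xa = extract_features_batch(coords, self.config)
        l1 = list(self.level1.classes)
        g = l1.index(GROUP_LABEL)
        out = np.zeros((len(coords), len(EXPRESSIONS)))
        for i in range(len(coords)):
            q = self.level1.distribution(Xd[i], Xa[i])
            r = self.level2.distribution(Xd[i], Xa[i])
            for c, lab in enumerate(l1):
                if c == g:
                    continue
                out[i, EXPRESSIONS.index(lab)] = q[c]
            for c, lab in enumerate(self.group):
                out[i, EXPRESSIONS.index(lab)] = q[g] * r[c]
        labels = [EXPRESSIONS[int(np.argmax(row))] for row in out]
        return labels, out

    def to_dict(self) -> dict:
        return {
            "format_version": 1,
            "kind": self.kind,
            "feature_config": self.config.to_dict(),
            "group": list(self.group),
            "level1": self.level1.to_dict(),
            "level2": self.level2.to_dict(),
            "training_seed": self.training_seed,
        }


@dataclass
class FlatModel:
    """Single-stage 6-class dual-stream model (the no-hierarchy baseline)."""

    pair: StreamPair
    config: FeatureConfig
    training_seed: Optional[int] = None

    kind = "flat"

    def predict(self, landmarks: np.ndarray):
        label, dist = self.predict_batch(np.asarray(landmarks)[None, :, :])
        return label[0], dist[0]

    def predict_batch(self, coords: np.ndarray):
        Xd, Xa = extract_features_batch(coords, self.config)
        out = np.stack(
            [self.pair.distribution(Xd[i], Xa[i]) for i in range(len(coords))]
        )
        labels = [self.pair.classes[int(np.argmax(row))] for row in out]
        return labels, out

    def to_dict(self) -> dict:
        return {
            "format_version": 1,
            "kind": self.kind,
            "feature_config": self.config.to_dict(),
            "level1": self.pair.to_dict(),
            "training_seed": self.training_seed,
        }


def model_from_dict(d: dict):
    """Inverse of ``to_dict`` for both model kinds."""
    config = FeatureConfig.from_dict(d["feature_config"])
    if d["kind"] == "hierarchical":
        return HierarchicalModel(
            StreamPair.from_dict(d["level1"]),
            StreamPair.from_dict(d["level2"]),
            config,
            d.get("training_seed"),
            tuple(d.get("group", DEFAULT_GROUP)),
        )
    if d["kind"] == "flat":
        return FlatModel(StreamPair.from_dict(d["level1"]), config, d.get("training_seed"))
    raise FerError(f"unknown model kind {d['kind']!r}")


def _require_all_classes(dataset: Dataset):
    present = set(dataset.labels)
    missing = [c for c in EXPRESSIONS if c not in present]
    if missing:
        raise FerError(f"training data is missing expression classes: {missing}")


def train_hierarchical(
    dataset: Dataset,
    params: ForestParams | None = None,
    fusion: FusionWeights | None = None,
    config: FeatureConfig | None = None,
    rng: np.random.Generator | None = None,
    group: Sequence[str] = DEFAULT_GROUP,
    training_seed: Optional[int] = None,
) -> HierarchicalModel:
    """Train the two-level model.

    Level 1 sees every sample, with the ``group`` expressions relabeled to a
    single group class; level 2 is trained only on the group's samples.  The
    level-1 vocabulary lists the solo classes in canonical order followed by
    the group label; ``group`` is configurable for alternative hierarchy
    readings (e.g., placing surprise inside the group).
    """
    params = params or ForestParams()
    fusion = fusion or FusionWeights()
    config = config or default_config()
    rng = rng if rng is not None else np.random.default_rng()
    _require_all_classes(dataset)
    group = tuple(group)
    solo = tuple(c for c in EXPRESSIONS if c not in group)
    level1_classes = solo + (GROUP_LABEL,)

    Xd, Xa = extract_features_batch(dataset.coords, config)
    labels = np.asarray(dataset.labels)
    y1 = np.array(
        [level1_classes.index(GROUP_LABEL if lab in group else lab) for lab in labels],
        dtype=np.intp,
    )
    in_group = np.isin(labels, group)
    y2 = np.array([group.index(lab) for lab in labels[in_group]], dtype=np.intp)

    level1 = _train_pair(Xd, Xa, y1, level1_classes, params, fusion, rng)
    level2 = _train_pair(Xd[in_group], Xa[in_group], y2, group, params, fusion, rng)
    return HierarchicalModel(level1, level2, config, training_seed, group)


def train_single(
    dataset: Dataset,
    params: ForestParams | None = None,
    fusion: FusionWeights | None = None,
    config: FeatureConfig | None = None,
    rng: np.random.Generator | None = None,
    training_seed: Optional[int] = None,
) -> FlatModel:
    """Train the flat 6-class dual-stream baseline (no hierarchy)."""
    params = params or ForestParams()
    fusion = fusion or FusionWeights()
    config = config or default_config()
    rng = rng if rng is not None else np.random.default_rng()
    _require_all_classes(dataset)
    Xd, Xa = extract_features_batch(dataset.coords, config)
    y = dataset.label_indices()
    pair = _train_pair(Xd, Xa, y, EXPRESSIONS, params, fusion, rng)
    return FlatModel(pair, config, training_seed)
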