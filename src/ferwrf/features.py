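"""Similarity-invariant geometric descriptors over landmark triples.

For a triple of landmarks {i, j, k} define the two vectors v_ij (from i to j)
and v_jk (from j to k), sharing the vertex j.  Two scalar descriptors are
computed per triple:

* distance ratio   ``||v_ij|| / ||v_jk||``
* angle relation   the unsigned angle between v_ij and v_jk, in [0, pi]

Both are invariant under similarity transforms of the face (rotation,
uniform scale, translation), so raw pixel coordinates can be used directly:
head pose in the image plane and camera distance do not perturb the features.

The default configuration provides 84 distance-ratio triples and 88
angle-relation triples drawn from the influential regions for expression:
mouth (48-67), jaw/chin (0-16), eyes (36-47) and eyebrows (17-26).  The
triple list is a packaged, versioned reconstruction constrained only by
those dimensionalities and regions; it is not learned from data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np

from .exceptions import ContractError, DegenerateGeometryError, FerError
from .landmarks import N_LANDMARKS

#: Guard on vector norms; shorter vectors are treated as degenerate geometry.
EPSILON = 1e-9

#: Landmark index ranges of the influential regions (inclusive bounds).
REGIONS = {
    "jaw": range(0, 17),
    "eyebrows": range(17, 27),
    "eyes": range(36, 48),
    "mouth": range(48, 68),
}

INFLUENTIAL_INDICES = frozenset(i for r in REGIONS.values() for i in r)

_DEFAULT_CONFIG_RESOURCE = "default_triples.json"


def _check_triple(t: Sequence[int]) -> tuple[int, int, int]:
    i, j, k = (int(v) for v in t)
    if len({i, j, k}) != 3:
        raise FerError(f"triple {(i, j, k)} must have pairwise distinct indices")
    for v in (i, j, k):
        if not 0 <= v < N_LANDMARKS:
            raise FerError(f"landmark index {v} outside [0, {N_LANDMARKS - 1}]")
    return (i, j, k)


@dataclass(frozen=True)
class FeatureConfig:
    """Ordered landmark-triple lists for the two feature streams."""

    distratio_triples: tuple[tuple[int, int, int], ...]
    anglerelat_triples: tuple[tuple[int, int, int], ...]

    def __post_init__(self):
        object.__setattr__(
            self, "distratio_triples",
            tuple(_check_triple(t) for t in self.distratio_triples),
        )
        object.__setattr__(
            self, "anglerelat_triples",
            tuple(_check_triple(t) for t in self.anglerelat_triples),
        )

    @property
    def n_distratio(self) -> int:
        return len(self.distratio_triples)

    @property
    def n_anglerelat(self) -> int:
        return len(self.anglerelat_triples)

    def to_dict(self) -> dict:
        return {
            "distratio_triples": [list(t) for t in self.distratio_triples],
            "anglerelat_triples": [list(t) for t in self.anglerelat_triples],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureConfig":
        return cls(
            tuple(tuple(t) for t in d["distratio_triples"]),
            tuple(tuple(t) for t in d["anglerelat_triples"]),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "FeatureConfig":
        with open(Path(path)) as fh:
            return cls.from_dict(json.load(fh))


def default_config() -> FeatureConfig:
    """The packaged default configuration: 84 distance-ratio and 88
    angle-relation triples over the mouth/jaw/eye/eyebrow regions."""
    text = resources.files("ferwrf.data").joinpath(_DEFAULT_CONFIG_RESOURCE).read_text()
    return FeatureConfig.from_dict(json.loads(text))


def _vectors(landmarks: np.ndarray, triple: Sequence[int]):
    i, j, k = triple
    pts = np.asarray(landmarks, dtype=float)
    return pts[j] - pts[i], pts[k] - pts[j]


def distance_ratio(landmarks: np.ndarray, triple: Sequence[int]) -> float:
    """``||v_ij|| / ||v_jk||`` for one triple; Euclidean norms."""
    v1, v2 = _vectors(landmarks, _check_triple(triple))
    n2 = np.linalg.norm(v2)
    if n2 <= EPSILON:
        raise DegenerateGeometryError(
            f"triple {tuple(triple)}: landmarks j and k coincide (|v_jk| = {n2:g})"
        )
    return float(np.linalg.norm(v1) / n2)


def angle_relation(landmarks: np.ndarray, triple: Sequence[int]) -> float:
    """Unsigned angle in [0, pi] between v_ij and v_jk, via a clamped arccos."""
    v1, v2 = _vectors(landmarks, _check_triple(triple))
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 <= EPSILON or n2 <= EPSILON:
        raise DegenerateGeometryError(
            f"triple {tuple(triple)}: degenerate vector (|v_ij| = {n1:g}, |v_jk| = {n2:g})"
        )
    cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.arccos(cosang))


def _extract_stream(coords: np.ndarray, triples: np.ndarray, stream: str) -> np.ndarray:
    """Vectorized per-stream extraction for coords of shape (n, 68, 2)."""
    i, j, k = triples[:, 0], triples[:, 1], triples[:, 2]
    v1 = coords[:, j, :] - coords[:, i, :]  # (n, m, 2)
    v2 = coords[:, k, :] - coords[:, j, :]
    n1 = np.linalg.norm(v1, axis=2)
    n2 = np.linalg.norm(v2, axis=2)
    bad = n2 <= EPSILON if stream == "distratio" else (n1 <= EPSILON) | (n2 <= EPSILON)
    if np.any(bad):
        row, col = np.argwhere(bad)[0]
        raise DegenerateGeometryError(
            f"sample {row}, {stream} triple index {col} "
            f"{tuple(triples[col])}: coincident landmarks"
        )
    if stream == "distratio":
        return n1 / n2
    cosang = np.clip(np.einsum("nmi,nmi->nm", v1, v2) / (n1 * n2), -1.0, 1.0)
    return np.arccos(cosang)


def extract_features(landmarks: np.ndarray, config: FeatureConfig):
    """Compute the two feature vectors for one face.

    Returns ``(distratio, anglerelat)`` as float arrays ordered like the
    config's triple lists.
    """
    pts = np.asarray(landmarks, dtype=float)
    if pts.shape != (N_LANDMARKS, 2):
        raise ContractError(f"expected ({N_LANDMARKS}, 2) landmarks, got {pts.shape}")
    d, a = extract_features_batch(pts[None, :, :], config)
    return d[0], a[0]


def extract_features_batch(coords: np.ndarray, config: FeatureConfig):
    """Feature matrices ``(n, n_distratio)`` and ``(n, n_anglerelat)`` for a
    stack of faces ``(n, 68, 2)``."""
    coords = np.asarray(coords, dtype=float)
    dist = _extract_stream(coords, np.asarray(config.distratio_triples), "distratio")
    ang = _extract_stream(coords, np.asarray(config.anglerelat_triples), "anglerelat")
    return dist, ang
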