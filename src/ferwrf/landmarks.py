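"""Labeled 68-point facial landmark datasets: I/O, validation, transforms.

A face observation is an ordered set of 68 (x, y) landmark points in pixel
coordinates, following the standard 68-point annotation ordering (jaw 0-16,
brows 17-26, nose 27-35, eyes 36-47, mouth 48-67), with x growing rightward
and y growing downward.  Raw pixel coordinates are preserved at I/O time:
no centering or rescaling is applied, because the geometric descriptors
computed downstream are invariant to similarity transforms.

The on-disk CSV schema is::

    subject_id,label,x0,y0,x1,y1,...,x67,y67

and the JSON dialect is an array of records
``{"subject_id": ..., "label": ..., "points": [[x, y], ...]}``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .exceptions import FerError, LabelVocabularyError, LandmarkFormatError

#: Closed vocabulary of the six basic expressions, in canonical (alphabetical)
#: order.  Class indices used throughout the package refer to this ordering.
EXPRESSIONS: tuple[str, ...] = (
    "anger",
    "disgust",
    "fear",
    "happiness",
    "sadness",
    "surprise",
)

N_LANDMARKS = 68

_CSV_COLUMNS = ["subject_id", "label"] + [
    f"{axis}{i}" for i in range(N_LANDMARKS) for axis in ("x", "y")
]


def validate_landmarks(points: np.ndarray) -> np.ndarray:
    """Validate and coerce one landmark set to a float64 ``(68, 2)`` array.

    Raises
    ------
    LandmarkFormatError
        If the shape is wrong, any coordinate is non-finite, or all points
        coincide.
    """
    arr = np.asarray(points, dtype=float)
    if arr.shape != (N_LANDMARKS, 2):
        raise LandmarkFormatError(
            f"expected {N_LANDMARKS} (x, y) points, got array of shape {arr.shape}"
        )
    if not np.all(np.isfinite(arr)):
        raise LandmarkFormatError("landmark coordinates must be finite")
    if np.allclose(arr, arr[0], atol=0.0):
        raise LandmarkFormatError("all 68 landmarks are identical")
    return arr


@dataclass(frozen=True)
class LabeledSample:
    """One face observation: landmarks, expression label, subject identifier."""

    landmarks: np.ndarray  # (68, 2) float64
    label: str
    subject_id: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "landmarks", validate_landmarks(self.landmarks))
        if self.label not in EXPRESSIONS:
            raise LabelVocabularyError(
                f"unknown expression label {self.label!r}; expected one of {EXPRESSIONS}"
            )
        if not self.subject_id:
            raise FerError("subject_id must be non-empty")


class Dataset:
    """An ordered collection of labeled landmark samples.

    Stored columnar for speed: ``coords`` is ``(n, 68, 2)``, ``labels`` and
    ``subjects`` are length-``n`` string arrays.
    """

    def __init__(self, coords: np.ndarray, labels: Sequence[str], subjects: Sequence[str]):
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 3 or coords.shape[1:] != (N_LANDMARKS, 2):
            raise LandmarkFormatError(
                f"coords must have shape (n, {N_LANDMARKS}, 2), got {coords.shape}"
            )
        labels = np.asarray(labels, dtype=object)
        subjects = np.asarray(subjects, dtype=object)
        if not (len(coords) == len(labels) == len(subjects)):
            raise FerError("coords, labels and subjects must have equal length")
        bad = set(labels) - set(EXPRESSIONS)
        if bad:
            raise LabelVocabularyError(f"unknown expression labels: {sorted(bad)}")
        for i in range(len(coords)):
            if not np.all(np.isfinite(coords[i])):
                raise LandmarkFormatError(f"non-finite coordinate in row {i}")
            if not subjects[i]:
                raise FerError(f"empty subject_id in row {i}")
        self.coords = coords
        self.labels = labels
        self.subjects = subjects

    def __len__(self) -> int:
        return len(self.labels)

    def __getitem__(self, i: int) -> LabeledSample:
        return LabeledSample(self.coords[i], str(self.labels[i]), str(self.subjects[i]))

    def __iter__(self) -> Iterator[LabeledSample]:
        for i in range(len(self)):
            yield self[i]

    def subset(self, rows) -> "Dataset":
        rows = np.asarray(rows)
        return Dataset(self.coords[rows], self.labels[rows], self.subjects[rows])

    def label_indices(self, vocabulary: Sequence[str] = EXPRESSIONS) -> np.ndarray:
        """Integer class index of every sample under ``vocabulary``."""
        lut = {lab: i for i, lab in enumerate(vocabulary)}
        try:
            return np.array([lut[lab] for lab in self.labels], dtype=np.intp)
        except KeyError as exc:  # pragma: no cover - guarded by __init__
            raise LabelVocabularyError(str(exc)) from exc

    @classmethod
    def from_samples(cls, samples: Sequence[LabeledSample]) -> "Dataset":
        if len(samples) == 0:
            return cls(np.empty((0, N_LANDMARKS, 2)), [], [])
        return cls(
            np.stack([s.landmarks for s in samples]),
            [s.label for s in samples],
            [s.subject_id for s in samples],
        )


def _infer_dialect(path: Path, dialect: str | None) -> str:
    if dialect is not None:
        if dialect not in ("csv", "json"):
            raise FerError(f"unknown dialect {dialect!r}")
        return dialect
    return "json" if path.suffix.lower() == ".json" else "csv"


def read_landmark_table(path, dialect: str | None = None) -> Dataset:
    """Read a labeled landmark table from CSV or JSON.

    The dialect is inferred from the file suffix when not given.  Errors name
    the offending row.
    """
    path = Path(path)
    dialect = _infer_dialect(path, dialect)
    if dialect == "csv":
        df = pd.read_csv(path, dtype={"subject_id": str, "label": str})
        missing = [c for c in _CSV_COLUMNS if c not in df.columns]
        extra = [c for c in df.columns if c not in _CSV_COLUMNS]
        if missing or extra:
            raise LandmarkFormatError(
                f"{path}: bad header; missing columns {missing[:5]}, "
                f"unexpected columns {extra[:5]}"
            )
        coord_cols = _CSV_COLUMNS[2:]
        try:
            coords = df[coord_cols].to_numpy(dtype=float)
        except ValueError as exc:
            raise LandmarkFormatError(f"{path}: non-numeric coordinate ({exc})") from exc
        coords = coords.reshape(len(df), N_LANDMARKS, 2)
        return Dataset(coords, df["label"].tolist(), df["subject_id"].tolist())

    with open(path) as fh:
        records = json.load(fh)
    if not isinstance(records, list):
        raise LandmarkFormatError(f"{path}: expected a JSON array of records")
    coords, labels, subjects = [], [], []
    for i, rec in enumerate(records):
        pts = np.asarray(rec.get("points", []), dtype=float)
        if pts.shape != (N_LANDMARKS, 2):
            raise LandmarkFormatError(
                f"{path}: record {i} has point array of shape {pts.shape}, "
                f"expected ({N_LANDMARKS}, 2)"
            )
        coords.append(pts)
        labels.append(rec.get("label"))
        subjects.append(rec.get("subject_id"))
    if not records:
        return Dataset(np.empty((0, N_LANDMARKS, 2)), [], [])
    return Dataset(np.stack(coords), labels, subjects)


def write_landmark_table(dataset: Dataset, path, dialect: str | None = None) -> None:
    """Write a dataset to CSV or JSON, losslessly re-readable by
    :func:`read_landmark_table` (coordinates round-trip via ``repr`` floats)."""
    path = Path(path)
    dialect = _infer_dialect(path, dialect)
    if dialect == "csv":
        flat = dataset.coords.reshape(len(dataset), N_LANDMARKS * 2)
        df = pd.DataFrame(flat, columns=_CSV_COLUMNS[2:])
        df.insert(0, "subject_id", dataset.subjects)
        df.insert(1, "label", dataset.labels)
        df.to_csv(path, index=False, float_format="%.17g")
    else:
        records = [
            {
                "subject_id": str(dataset.subjects[i]),
                "label": str(dataset.labels[i]),
                "points": dataset.coords[i].tolist(),
            }
            for i in range(len(dataset))
        ]
        with open(path, "w") as fh:
            json.dump(records, fh)


def rotation_matrix(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


def apply_similarity_transform(
    landmarks: np.ndarray,
    rotation: float = 0.0,
    scale: float = 1.0,
    translation=(0.0, 0.0),
) -> np.ndarray:
    """Map every point p to ``scale * R(rotation) @ p + translation``.

    ``rotation`` is in radians (counter-clockwise in a y-up frame; in image
    coordinates the visual rotation is clockwise, which is irrelevant to the
    invariance properties tested downstream).
    """
    if scale <= 0:
        raise FerError(f"scale must be positive, got {scale}")
    pts = np.asarray(landmarks, dtype=float)
    out = scale * pts @ rotation_matrix(rotation).T + np.asarray(translation, dtype=float)
    return out
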