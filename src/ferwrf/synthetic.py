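"""Synthetic labeled 68-point landmark datasets.

Real expression corpora are image databases; this generator emulates only
their landmark-level geometry so the rest of the package is testable without
any download.  A fixed neutral template face (inter-ocular distance 200 px)
is deformed by one hand-designed displacement field per expression, loosely
following facial-action descriptions: happiness raises the mouth corners,
surprise raises the brows and drops the jaw, fear raises/stretches, anger
lowers and knits the brows, disgust raises the upper lip and nose, sadness
depresses the lip corners and raises the inner brows.  The fields are
plausibility-only: no claim is made that they match any real database's
geometry.

Sampling stacks, in order: expression displacement (scaled by a per-sample
intensity), a per-subject landmark offset field (Gaussian, sigma_subj),
per-sample landmark noise (Gaussian, sigma), and finally a random similarity
transform (rotation, scale, translation) emulating head pose and camera
distance.  Because the downstream features are similarity-invariant, the
pose jitter stresses the pipeline without moving class boundaries.

The ``confusability`` parameter kappa in [0, 1] blends the anger, disgust
and sadness displacement fields toward their common centroid, making those
three classes progressively harder to separate (kappa = 1 collapses them
onto a single prototype).  This mirrors the empirical observation that those
expressions share similar facial geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .exceptions import FerError
from .landmarks import EXPRESSIONS, N_LANDMARKS, Dataset, apply_similarity_transform

#: Default per-sample landmark noise, pixels.
DEFAULT_NOISE_SIGMA = 1.5
#: Default per-subject offset field sigma, pixels.
DEFAULT_SUBJECT_SIGMA = 2.0

_ADS = ("anger", "disgust", "sadness")


def _build_template() -> np.ndarray:
    """Neutral 68-point face; x right, y down, origin later shifted into the
    image quadrant.  Eye centers at (-100, 0) and (100, 0): inter-ocular
    distance 200 px."""
    pts = np.zeros((N_LANDMARKS, 2))
    # jaw 0-16: half ellipse from left temple to right temple through the chin
    t = np.linspace(0.0, 1.0, 17)
    pts[0:17, 0] = -160.0 * np.cos(np.pi * t)
    pts[0:17, 1] = 220.0 * np.sin(np.pi * t)
    # eyebrows 17-21 (left) and 22-26 (right), gently arched
    bx = np.linspace(-145.0, -55.0, 5)
    arch = -10.0 * np.sin(np.pi * np.linspace(0.1, 0.9, 5))
    pts[17:22, 0] = bx
    pts[17:22, 1] = -60.0 + arch
    pts[22:27, 0] = -bx[::-1]
    pts[22:27, 1] = -60.0 + arch[::-1]
    # nose bridge 27-30 and nostril line 31-35
    pts[27:31, 0] = 0.0
    pts[27:31, 1] = np.linspace(-40.0, 60.0, 4)
    pts[31:36, 0] = np.array([-30.0, -15.0, 0.0, 15.0, 30.0])
    pts[31:36, 1] = np.array([80.0, 83.0, 85.0, 83.0, 80.0])
    # eyes 36-41 (left, from outer corner clockwise) and 42-47 (right)
    left_eye = np.array(
        [[-125, 0], [-112, -8], [-88, -8], [-75, 0], [-88, 8], [-112, 8]], dtype=float
    )
    pts[36:42] = left_eye
    right_eye = left_eye * np.array([-1.0, 1.0])
    pts[42:48] = right_eye[[3, 2, 1, 0, 5, 4]]  # keep inner->outer ordering convention
    # outer lip 48-59 (from left corner, over the top, back along the bottom)
    pts[48:60] = np.array(
        [
            [-50, 140], [-30, 128], [-12, 122], [0, 120], [12, 122], [30, 128],
            [50, 140], [30, 155], [12, 160], [0, 162], [-12, 160], [-30, 155],
        ],
        dtype=float,
    )
    # inner lip 60-67
    pts[60:68] = np.array(
        [
            [-40, 140], [-15, 133], [0, 131], [15, 133],
            [40, 140], [15, 148], [0, 150], [-15, 148],
        ],
        dtype=float,
    )
    # shift into a 640x480-like image quadrant
    return pts + np.array([320.0, 240.0])


def _set(rows, dx=0.0, dy=0.0, out=None):
    out[list(rows), 0] += dx
    out[list(rows), 1] += dy
    return out


def _build_displacements() -> dict[str, np.ndarray]:
    """One (68, 2) displacement field per expression, y-down convention
    (negative dy moves a landmark up the face).  Magnitudes are kept within
    30 px, i.e. 15% of the inter-ocular distance, at intensity 1."""
    D: dict[str, np.ndarray] = {e: np.zeros((N_LANDMARKS, 2)) for e in EXPRESSIONS}

    d = D["happiness"]  # mouth corners up and out, cheeks narrow the eyes
    _set([48, 60], dx=-8, dy=-18, out=d)
    _set([54, 64], dx=8, dy=-18, out=d)
    _set([49, 59, 61, 67], dy=-10, out=d)
    _set([53, 55, 63, 65], dy=-10, out=d)
    _set([37, 38, 43, 44], dy=3, out=d)
    _set([40, 41, 46, 47], dy=-3, out=d)

    d = D["surprise"]  # brow raise, eye widening, jaw drop
    _set(range(17, 27), dy=-20, out=d)
    _set([37, 38, 43, 44], dy=-4, out=d)
    _set([40, 41, 46, 47], dy=4, out=d)
    _set([55, 56, 57, 58, 59], dy=25, out=d)
    _set([65, 66, 67], dy=22, out=d)
    _set([7, 8, 9], dy=15, out=d)

    d = D["fear"]  # brows raised and knitted, lips stretched, mouth ajar
    _set(range(17, 27), dy=-12, out=d)
    _set([21], dx=6, dy=-6, out=d)
    _set([22], dx=-6, dy=-6, out=d)
    _set([48, 60], dx=-12, out=d)
    _set([54, 64], dx=12, out=d)
    _set([55, 56, 57, 58, 59, 65, 66, 67], dy=10, out=d)

    d = D["anger"]  # brows lowered and drawn in, lips pressed
    _set(range(17, 27), dy=12, out=d)
    _set([20, 21], dx=8, dy=4, out=d)
    _set([22, 23], dx=-8, dy=4, out=d)
    _set([49, 50, 51, 52, 53, 61, 62, 63], dy=4, out=d)
    _set([55, 56, 57, 58, 59, 65, 66, 67], dy=-6, out=d)
    _set([48, 54], dy=3, out=d)

    d = D["disgust"]  # upper lip and nose raised, slight brow lowering
    _set([49, 50, 51, 52, 53, 61, 62, 63], dy=-12, out=d)
    _set(range(31, 36), dy=-8, out=d)
    _set(range(17, 27), dy=6, out=d)
    _set([55, 56, 57, 58, 59, 65, 66, 67], dy=-4, out=d)

    d = D["sadness"]  # lip corners depressed, inner brows raised
    _set([48, 60], dy=14, out=d)
    _set([54, 64], dy=14, out=d)
    _set([49, 53, 59, 55], dy=7, out=d)
    _set([21, 22], dy=-12, out=d)
    _set([20, 23], dy=-6, out=d)
    _set([57, 66], dy=-4, out=d)
    return D


@lru_cache(maxsize=1)
def neutral_template() -> np.ndarray:
    return _build_template()


@lru_cache(maxsize=1)
def _displacements() -> dict[str, np.ndarray]:
    return _build_displacements()


def make_prototype(expression: str, intensity: float = 1.0, kappa: float = 0.0) -> np.ndarray:
    """Prototype landmark set: neutral + intensity * displacement.

    For anger/disgust/sadness the displacement is first blended toward the
    centroid of the three fields by the confusability factor ``kappa``
    (kappa = 1 makes the three prototypes identical).
    """
    if expression not in EXPRESSIONS:
        raise FerError(f"unknown expression {expression!r}")
    if not 0.0 <= intensity <= 1.0:
        raise FerError(f"intensity must lie in [0, 1], got {intensity}")
    if not 0.0 <= kappa <= 1.0:
        raise FerError(f"kappa must lie in [0, 1], got {kappa}")
    disp = _displacements()[expression].copy()
    if expression in _ADS and kappa > 0.0:
        centroid = sum(_displacements()[e] for e in _ADS) / len(_ADS)
        disp = (1.0 - kappa) * disp + kappa * centroid
    return neutral_template() + intensity * disp


@dataclass
class SimulationParams:
    """Stated world of the packaged benchmark.

    Defaults: 12 subjects (the size of a small driver-monitoring cohort),
    20 samples per class per subject, 1.5 px landmark noise on a 200 px
    inter-ocular template, 2 px subject offsets, confusability 0.5, apex-like
    intensities in [0.7, 1], pose jitter of +/-15 degrees rotation, scale in
    [0.8, 1.25] and translation within +/-50 px, seed 42.
    """

    n_subjects: int = 12
    n_per_class_per_subject: int = 20
    noise_sigma: float = DEFAULT_NOISE_SIGMA
    subject_sigma: float = DEFAULT_SUBJECT_SIGMA
    confusability: float = 0.5
    intensity_range: tuple[float, float] = (0.7, 1.0)
    rotation_range: tuple[float, float] = (-np.pi / 12, np.pi / 12)
    scale_range: tuple[float, float] = (0.8, 1.25)
    translation_range: tuple[float, float] = (-50.0, 50.0)
    seed: int = 42

    def __post_init__(self):
        if self.noise_sigma < 0 or self.subject_sigma < 0:
            raise FerError("noise sigmas must be non-negative")
        if not 0.0 <= self.confusability <= 1.0:
            raise FerError("confusability must lie in [0, 1]")
        if self.n_subjects < 1 or self.n_per_class_per_subject < 1:
            raise FerError("cohort sizes must be positive")


def sample_dataset(params: SimulationParams | None = None) -> Dataset:
    """Draw a labeled synthetic dataset; deterministic given ``params.seed``.

    Draw order (stable across versions): per subject, one offset field; then
    per expression (canonical order) and repetition: intensity, landmark
    noise, rotation, scale, translation.
    """
    params = params or SimulationParams()
    rng = np.random.default_rng(params.seed)
    coords, labels, subjects = [], [], []
    for s in range(params.n_subjects):
        sid = f"S{s:02d}"
        # sigma scales a unit draw so the stream is identical across sigmas
        offset = params.subject_sigma * rng.standard_normal((N_LANDMARKS, 2))
        for expression in EXPRESSIONS:
            for _ in range(params.n_per_class_per_subject):
                intensity = float(rng.uniform(*params.intensity_range))
                pts = make_prototype(expression, intensity, params.confusability)
                pts = pts + offset
                pts = pts + params.noise_sigma * rng.standard_normal((N_LANDMARKS, 2))
                rot = float(rng.uniform(*params.rotation_range))
                scale = float(rng.uniform(*params.scale_range))
                trans = rng.uniform(*params.translation_range, size=2)
                coords.append(apply_similarity_transform(pts, rot, scale, trans))
                labels.append(expression)
                subjects.append(sid)
    return Dataset(np.stack(coords), labels, subjects)
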