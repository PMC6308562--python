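import numpy as np
import pytest

from ferwrf import (
    Dataset,
    ForestParams,
    SimulationParams,
    TreeParams,
    default_config,
    sample_dataset,
)
from ferwrf.synthetic import neutral_template


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def template():
    return neutral_template()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small but fully populated 6-class dataset: 4 subjects x 3 per class."""
    return sample_dataset(
        SimulationParams(n_subjects=4, n_per_class_per_subject=3, seed=7)
    )


@pytest.fixture(scope="session")
def clean_dataset():
    """Noise-free, pose-free, non-confusable dataset (perfectly separable)."""
    return sample_dataset(
        SimulationParams(
            n_subjects=3,
            n_per_class_per_subject=3,
            noise_sigma=0.0,
            subject_sigma=0.0,
            confusability=0.0,
            intensity_range=(1.0, 1.0),
            rotation_range=(0.0, 0.0),
            scale_range=(1.0, 1.0),
            translation_range=(0.0, 0.0),
            seed=3,
        )
    )


@pytest.fixture()
def small_forest_params():
    return ForestParams(
        n_trees=8,
        tree_params=TreeParams(max_depth=8),
    )


def random_dataset(rng, n=5):
    """Valid random landmark dataset (for I/O round-trips)."""
    coords = rng.uniform(0, 640, size=(n, 68, 2))
    labels = rng.choice(
        ["anger", "disgust", "fear", "happiness", "sadness", "surprise"], size=n
    )
    subjects = [f"P{i % 3}" for i in range(n)]
    return Dataset(coords, list(labels), subjects)
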