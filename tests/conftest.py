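import numpy as np
import pytest
from hypothesis import settings

from comorbmtl import TaskCollection, TaskData, split_centers

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from comorbmtl.synthetic import SimConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_collection(rng):
    """Two tasks, 30 subjects, 4 features, 3 centers."""
    X = rng.standard_normal((30, 4))
    centers = np.repeat(["a", "b", "c"], 10)
    y0 = X @ np.array([1.0, -0.5, 0.0, 0.0]) + 0.3 * rng.standard_normal(30)
    y1 = X @ np.array([0.8, -0.4, 0.0, 0.0]) + 0.3 * rng.standard_normal(30)
    return TaskCollection([TaskData(X, y0, "pain", centers),
                           TaskData(X.copy(), y1, "depression", centers)])


@pytest.fixture(scope="session")
def planted_dataset():
    """Moderate planted-signal dataset with its ground truth and split."""
    cfg = SimConfig(n_subjects=400, n_features=30, effect_size=0.4, seed=7)
    data, truth = generate_dataset(cfg)
    dev_labels, hold_labels = split_centers(data.tasks[0].centers, seed=7)
    return data, truth, dev_labels, hold_labels
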