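from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import pulsescale as ps

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def clean_window() -> ps.RRSeries:
    """One clean 5-min synthetic RR window with default dynamics."""
    return ps.gen_rr(ps.SyntheticConfig(), 310.0, seed=42)


@pytest.fixture(scope="session")
def separable_dataset():
    """Default class-separated labeled dataset, 50 windows per class."""
    return ps.gen_labeled_dataset(50, seed=20)


@pytest.fixture(scope="session")
def separable_run(separable_dataset):
    """Full 250-split RFE + SVM experiment on the separable dataset."""
    X, y = separable_dataset
    plan = ps.make_splits(y, folds=5, repeats=50, base_seed=20)
    return ps.run_experiment(X, y, plan, base_seed=20)
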