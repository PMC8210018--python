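import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from survsig import ExpressionMatrix, SurvivalTable
from survsig.simulate import SyntheticSpec, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_cohort():
    """8 samples, 3 features, continuous times, mixed censoring."""
    rng = np.random.default_rng(7)
    samples = [f"S{i}" for i in range(8)]
    feats = ["gA", "gB", "gC"]
    expr = ExpressionMatrix(pd.DataFrame(
        rng.lognormal(mean=2.0, sigma=0.8, size=(8, 3)),
        index=samples, columns=feats,
    ))
    time = pd.Series([31.5, 84.2, 12.9, 150.4, 66.1, 240.8, 45.3, 110.0],
                     index=samples, name="time")
    status = pd.Series([1, 0, 1, 1, 0, 1, 1, 0.0], index=samples, name="status")
    return expr, SurvivalTable(time, status)


@pytest.fixture(scope="session")
def medium_cohort():
    """150 samples, 30 features, 3 planted effects; reused across tests."""
    spec = SyntheticSpec.with_planted(
        n_samples=150, n_features=30, n_true=3, beta=0.8,
        censoring_fraction=0.3, seed=42,
    )
    return generate_cohort(spec)
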