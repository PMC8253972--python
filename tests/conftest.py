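from pathlib import Path

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dyadprint import SimilarityMatrix, SyntheticSpec, simulate_cohort

settings.register_profile(
    "det", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture
def rng():
    return np.random.default_rng(20210611)


@pytest.fixture(scope="session")
def fixture_dir():
    return Path(__file__).parent / "data"


def random_similarity(rng: np.random.Generator, n: int) -> SimilarityMatrix:
    """Exchangeable similarity matrix with iid entries (null structure)."""
    vals = rng.uniform(-1, 1, size=(n, n))
    return SimilarityMatrix([f"c{i}" for i in range(n)], [f"p{i}" for i in range(n)], vals)


@pytest.fixture(scope="session")
def small_study():
    """12-dyad, 33-node (3 per network) study with moderate transmission."""
    return simulate_cohort(SyntheticSpec(n_dyads=12, n_nodes=33, alpha=0.6, seed=7))
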