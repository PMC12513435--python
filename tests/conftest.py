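import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from concise_networks import PathCorpus, TrigramCounts, posterior_dynamics


@pytest.fixture
def small_counts() -> TrigramCounts:
    """A 2x2 count table with one strong-memory and one mixed predecessor."""
    return TrigramCounts("J", ("a", "b"), ("x", "y"), np.array([[3.0, 1.0], [1.0, 1.0]]))


@pytest.fixture
def diagonal_counts() -> TrigramCounts:
    """Perfect-memory counts: each predecessor maps to its own successor."""
    return TrigramCounts("J", ("a", "b"), ("x", "y"), np.array([[2.0, 0.0], [0.0, 2.0]]))


@pytest.fixture
def chain_corpus() -> PathCorpus:
    return PathCorpus([(("A", "B", "C", "D"), 1.0)])


def random_counts(rng: np.random.Generator, n_succ: int = 5, n_pred: int = 5) -> TrigramCounts:
    """Random strictly-positive count table for property tests."""
    A = rng.integers(1, 20, size=(n_succ, n_pred)).astype(float)
    width = 2
    return TrigramCounts(
        "J",
        tuple(f"p{i:0{width}d}" for i in range(n_pred)),
        tuple(f"s{k:0{width}d}" for k in range(n_succ)),
        A,
    )
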