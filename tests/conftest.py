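import numpy as np
import pytest

from gtsurv.npmle import SurvivalDataset


@pytest.fixture
def disjoint_pair() -> SurvivalDataset:
    """Two disjoint strict intervals (0,1] and (1,2]."""
    return SurvivalDataset(left=np.array([0.0, 1.0]),
                           right=np.array([1.0, 2.0]),
                           X=np.zeros((2, 1)))


@pytest.fixture
def nested_pair() -> SurvivalDataset:
    """Overlapping intervals (0,2] and (1,2]; NPMLE puts all mass on (1,2]."""
    return SurvivalDataset(left=np.array([0.0, 1.0]),
                           right=np.array([2.0, 2.0]),
                           X=np.zeros((2, 1)))


@pytest.fixture
def exact_times() -> SurvivalDataset:
    """Degenerate intervals L == R: plain observed event times {1, 2, 3}."""
    t = np.array([1.0, 3.0, 2.0])
    return SurvivalDataset(left=t, right=t, X=np.zeros((3, 1)))


def random_interval_dataset(rng: np.random.Generator, n: int,
                            p: int = 1) -> SurvivalDataset:
    """Random mix of exact, interval-, left- and right-censored subjects."""
    T = rng.exponential(1.0, size=n)
    kind = rng.integers(0, 4, size=n)
    L = np.where(kind == 0, T, 0.0)
    R = np.where(kind == 0, T, np.inf)
    inter = kind == 1
    L = np.where(inter, T * rng.uniform(0.2, 0.9, n), L)
    R = np.where(inter, T + rng.uniform(0.1, 1.0, n), R)
    left = kind == 2
    L = np.where(left, 0.0, L)
    R = np.where(left, T + rng.uniform(0.0, 0.5, n), R)
    right = kind == 3
    L = np.where(right, T * rng.uniform(0.3, 1.0, n), L)
    R = np.where(right, np.inf, R)
    return SurvivalDataset(left=L, right=R,
                           X=rng.standard_normal((n, p)))
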