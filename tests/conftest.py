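import numpy as np
import pytest

from semelcoal import LifeHistory, from_survival

# survival schedule behind the published chinook head-count example
# (200,000-egg pool -> 10,000 -> 1,000 -> 800 -> 640 -> 512)
CHINOOK_SURVIVAL = (0.05, 0.1, 0.8, 0.8, 0.8)


@pytest.fixture(scope="session")
def worked_example() -> LifeHistory:
    """Chinook head-count example: 500 spawners, 200,000-egg pool."""
    return from_survival(500, 400, CHINOOK_SURVIVAL)


@pytest.fixture(scope="session")
def marsh_lh() -> LifeHistory:
    """Marsh Creek spring chinook contributions with the series-study death
    fractions; internally inconsistent with full bookkeeping (by design)."""
    return LifeHistory(
        p=np.array([0, 0, 0.04, 0.25, 0.71]),
        c=np.array([0, 0, 0.01, 0.05, 0.15]),
        N=100_000.0,
        phi=0.5,
    )


@pytest.fixture(scope="session")
def surface_lh() -> LifeHistory:
    """A representative point of the CES surface exploration."""
    return LifeHistory(
        p=np.array([0, 0, 0.1, 0.2, 0.7]),
        c=np.array([0, 0, 0.05, 0.1, 0.15]),
        N=1000.0,
    )


@pytest.fixture(scope="session")
def young_lh() -> LifeHistory:
    """Early-maturing life history (most spawning at age three)."""
    return LifeHistory(
        p=np.array([0, 0, 0.6, 0.3, 0.1]),
        c=np.array([0, 0, 0.2, 0.1, 0.02]),
        N=10_000.0,
    )


@pytest.fixture(scope="session")
def strict_lh() -> LifeHistory:
    """Fully bookkept life history with integer classes at N = 1000.

    N_i = (790, 90, 60, 40, 20), D = (700, 30, 20, 20, 20); satisfies
    sum(i * c_i) = 1 exactly, so the forward simulator accepts it.
    """
    return LifeHistory(
        p=np.array([0, 0, 0.2, 0.3, 0.5]),
        c=np.array([0.70, 0.03, 0.02, 0.02, 0.02]),
        N=1000.0,
    )


@pytest.fixture(scope="session")
def single_class_lh() -> LifeHistory:
    """Only the oldest class reproduces; equal class sizes, c_5 = 0.2."""
    return LifeHistory(
        p=np.array([0, 0, 0, 0, 1.0]),
        c=np.array([0, 0, 0, 0, 0.2]),
        N=1000.0,
    )
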