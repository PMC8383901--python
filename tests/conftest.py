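import numpy as np
import pytest

from agecoal import PiecewiseRate, SharingCounts, TimeGrid


@pytest.fixture
def two_epoch_rate() -> PiecewiseRate:
    """λ = 0.01 on [0, 50), 0.001 on [50, 1000): cumulative to 150 is 0.6."""
    return PiecewiseRate(TimeGrid(np.array([0.0, 50.0, 1000.0])), np.array([0.01, 0.001]))


@pytest.fixture
def narrow_bin_counts() -> SharingCounts:
    """63 shared / 37 not-shared observations, all at age ~100 (a narrow bin
    around 100 inside [0, 100.01]); closed-form MLE is -ln(0.37)/100."""
    grid = TimeGrid(np.array([0.0, 99.99, 100.01]))
    return SharingCounts(
        grid=grid,
        t0=0.0,
        blocks=[("1", 1, 1_000_001), ("1", 1_000_001, 2_000_001)],
        shared=np.array([[0.0, 33.0], [0.0, 30.0]]),
        notshared=np.array([[0.0, 20.0], [0.0, 17.0]]),
    )


def make_counts(grid, shared, notshared, t0=0.0, n_blocks=2):
    """Split totals evenly over n_blocks blocks."""
    shared = np.asarray(shared, float)
    notshared = np.asarray(notshared, float)
    return SharingCounts(
        grid=grid,
        t0=t0,
        blocks=[("1", 1 + i * 10**6, 1 + (i + 1) * 10**6) for i in range(n_blocks)],
        shared=np.tile(shared / n_blocks, (n_blocks, 1)),
        notshared=np.tile(notshared / n_blocks, (n_blocks, 1)),
    )
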