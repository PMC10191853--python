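import numpy as np
import pytest

from flashkin.dataset import FlashSeriesDataset, TimeGrid, WavenumberGrid


@pytest.fixture
def wn_grid():
    """Small fingerprint-window wavenumber grid."""
    return WavenumberGrid(np.linspace(1300.0, 1750.0, 12))


@pytest.fixture
def time_grid():
    """Coarse sampling: 50 us steps, 10 pre-flash samples, 30 ms post."""
    return TimeGrid(dt=50.0, n_samples=610, t0_index=10)


@pytest.fixture
def tiny_dataset(wn_grid):
    """4-flash dataset with deterministic (seeded) smooth content."""
    time = TimeGrid(dt=50.0, n_samples=60, t0_index=5)
    rng = np.random.default_rng(0)
    data = rng.normal(0.0, 1e-5, size=(4, 60, len(wn_grid)))
    return FlashSeriesDataset(data=data, time=time, wavenumbers=wn_grid,
                              metadata={"note": "fixture"})
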