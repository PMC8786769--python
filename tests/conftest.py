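import numpy as np
import pytest

from placidollt.preprocess import ProcessedROI


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def make_roi():
    """Factory for ProcessedROI from a 2-D grid (full mask by default)."""

    def _make(grid, mask=None):
        return ProcessedROI.from_grid(np.asarray(grid, dtype=float), mask=mask)

    return _make


@pytest.fixture
def random_roi_factory(rng):
    """Seeded random rectangular ROIs with integer grey levels."""

    def _make(height, width, low=0, high=256):
        grid = rng.integers(low, high, size=(height, width)).astype(float)
        return ProcessedROI.from_grid(grid)

    return _make
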