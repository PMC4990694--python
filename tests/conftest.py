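import numpy as np
import pytest

from pnpmrf.dictionary import build_dictionary, reduced_grid
from pnpmrf.schedule import build_default_schedule


@pytest.fixture(scope="session")
def default_schedule():
    return build_default_schedule()


@pytest.fixture(scope="session")
def small_dict(default_schedule):
    """Reduced 8x8x4x4 dictionary over B1 in 2..8 uT (no degenerate entries)."""
    grid = reduced_grid(8, 8, (10, 20, 30, 40))
    return build_dictionary(grid, default_schedule)


@pytest.fixture(scope="session")
def small_dict_with_zero_b1(default_schedule):
    """Reduced dictionary whose B1 axes include 0 (for void scenarios)."""
    grid = reduced_grid(8, 8, (0, 10, 20, 30, 40))
    return build_dictionary(grid, default_schedule)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
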