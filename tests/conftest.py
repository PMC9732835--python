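import numpy as np
import pytest

from columnscope import synthetic as syn


@pytest.fixture(scope="session")
def small_sheet():
    return syn.make_sheet(nx=32, ny=32, dx=0.5)


@pytest.fixture(scope="session")
def small_labels(small_sheet):
    return syn.plant_columns(small_sheet, {"PA": 0.8, "PW": 0.5,
                                           "DN": 0.8, "DF": 0.6}, seed=7)


@pytest.fixture(scope="session")
def p_only_labels(small_sheet):
    """Approach/withdrawal poles only (no disparity family)."""
    return syn.plant_columns(small_sheet, {"PA": 0.8, "PW": 0.8}, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
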