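import numpy as np
import pytest

from orchardmetrics.synthetic import OrchardLayout, simulate_scene


@pytest.fixture(scope="session")
def small_layout():
    """A 3x8 orchard block, no dead trees: small enough for fast tests,
    large enough to exercise row and column detection."""
    return OrchardLayout(
        n_rows=3,
        trees_per_row=(8, 8, 8),
        row_spacing=5.0,
        plant_spacing=4.0,
        field_length=40.0,
        field_width=15.0,
        dead_fraction=0.0,
    )


@pytest.fixture(scope="session")
def small_scene(small_layout):
    return simulate_scene(small_layout, gsd=3.31, seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
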