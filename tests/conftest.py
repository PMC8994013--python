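import numpy as np
import pytest

from echoseg import phantom as ph


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def default_phantom():
    """One rendered default-spec cycle, shared across tests (read-only)."""
    return ph.generate_phantom_sequence(ph.PhantomSpec(seed=11))


@pytest.fixture(scope="session")
def small_spec():
    """A small, fast-to-render spec for network-level tests."""
    return ph.PhantomSpec(n_frames=6, height=192, width=160,
                          center=(96.0, 80.0), semi_axis_long_ed=70.0,
                          semi_axis_short_ed=42.0, wall_thickness=8.0,
                          pixel_spacing=0.06, seed=5)
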