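import numpy as np
import pytest

from emtscreen import synthgen


@pytest.fixture(scope="session")
def default_model():
    return synthgen.EffectModel()


@pytest.fixture(scope="session")
def small_screen():
    """A compact 3-plate screen with 4 planted hits (shared across read-only tests)."""
    wells, model = synthgen.simulate_screen(n_plates=3, n_hits=4, effect=30.0, seed=11)
    return wells, model


@pytest.fixture(scope="session")
def desk_screen():
    """The default desk-scale fixture: 8 plates, 16 hits planted at 20 null-SD units."""
    base = synthgen.EffectModel()
    effect_mad = 20.0 * base.null_sd_over_mad
    wells, model = synthgen.simulate_screen(n_plates=8, n_hits=16, effect=effect_mad, seed=23)
    return wells, model


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
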