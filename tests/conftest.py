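import numpy as np
import pytest

from kneekin import synthetic as syn


@pytest.fixture(scope="session")
def knee_model():
    """Default native knee (unequal condyle radii, flat plateau)."""
    return syn.generate_knee_model()


@pytest.fixture(scope="session")
def symmetric_knee():
    """Mirror-symmetric knee: equal condyle radii, zero plateau varus."""
    spec = syn.KneeSpec(medial_condyle_radius=23.0, lateral_condyle_radius=23.0,
                        plateau_varus_angle=0.0)
    return syn.generate_knee_model(spec)


@pytest.fixture(scope="session")
def tka_model():
    return syn.generate_tka_model()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
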