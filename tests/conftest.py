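import numpy as np
import pytest

from myoseg import PhantomSpec, make_lv_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def clean_phantom():
    """Default clean LV phantom: (image, endo, epi, myo)."""
    return make_lv_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def small_phantom():
    """Small clean phantom for fast evolution tests."""
    spec = PhantomSpec(shape=(80, 80), center=(40.0, 40.0), r_endo=11.0, r_epi=19.0)
    return make_lv_phantom(spec)
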