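import numpy as np
import pytest

import jacint as J


@pytest.fixture(scope="session")
def phantom48():
    """Small noiseless phantom shared by geometry-level tests."""
    spec = J.PhantomSpec(shape=(48, 48, 48))
    img, lab = J.make_phantom(spec)
    return spec, img, lab


@pytest.fixture(scope="session")
def phantom64():
    spec = J.PhantomSpec(shape=(64, 64, 64))
    img, lab = J.make_phantom(spec)
    return spec, img, lab


@pytest.fixture(scope="session")
def atrophied64(phantom64):
    """Noiseless 64^3 pair with a -0.5% radial GM contraction."""
    spec, img, lab = phantom64
    followup, fwd, truth = J.apply_atrophy(img, lab, -0.5, mode="radial_gm",
                                           spec=spec)
    return spec, img, lab, followup, fwd, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
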