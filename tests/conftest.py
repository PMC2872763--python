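import numpy as np
import pytest

import ventpve as vp


@pytest.fixture(scope="session")
def small_phantom() -> vp.PhantomOutput:
    """96x96 single-ellipse phantom used by several unit tests."""
    spec = vp.PhantomSpec(
        shape=(96, 96), geometry="ellipse", semi_axes=(28.0, 14.0), seed=5
    )
    return vp.generate_phantom(spec)


@pytest.fixture(scope="session")
def default_phantom() -> vp.PhantomOutput:
    """Default 256x256 two-ellipse phantom."""
    return vp.generate_phantom(vp.PhantomSpec(seed=7))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
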