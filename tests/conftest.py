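import numpy as np
import pytest

from mousequant.phantom import (
    PhantomSpec,
    default_phantom_spec,
    generate_atlas_phantom,
)


@pytest.fixture(scope="session")
def spec04():
    """Default study conditions: 0.4 mm isotropic grid."""
    return default_phantom_spec()


@pytest.fixture(scope="session")
def atlas04(spec04):
    return generate_atlas_phantom(spec04, seed=0)


@pytest.fixture(scope="session")
def spec08():
    """Coarse (0.8 mm) conditions for fast registration unit tests."""
    return PhantomSpec(spacing_mm=0.8)


@pytest.fixture(scope="session")
def atlas08(spec08):
    return generate_atlas_phantom(spec08, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
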