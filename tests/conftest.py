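import numpy as np
import pytest

from wbcure.phantom import PhantomSpec, build_phantom


@pytest.fixture(scope="session")
def default_spec():
    return PhantomSpec(seed=42)


@pytest.fixture(scope="session")
def clean_session(default_spec):
    """Defect-free 7-contrast phantom session (shared, read-only)."""
    return build_phantom(default_spec)


@pytest.fixture(scope="session")
def noisefree_spec():
    return PhantomSpec(seed=7, noise_sigma_frac=0.0)


@pytest.fixture(scope="session")
def noisefree_session(noisefree_spec):
    return build_phantom(noisefree_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
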