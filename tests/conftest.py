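import numpy as np
import pytest

from nirpowder import build_sample_table, default_library, make_fixtures


@pytest.fixture(scope="session")
def library():
    return default_library()


@pytest.fixture(scope="session")
def design_records():
    return build_sample_table()


@pytest.fixture(scope="session")
def mini_bundle():
    """Miniature design + coarse-grid spectra (54 samples, 50 wavelengths)."""
    return make_fixtures(seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
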