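import numpy as np
import pytest

from gliomap.phantom import make_atlas_labels, make_phantom_subject


@pytest.fixture(scope="session")
def atlas():
    """Reference 64^3 parcellated atlas phantom, 2 mm isotropic."""
    return make_atlas_labels((64, 64, 64), (2.0, 2.0, 2.0), seed=0)


@pytest.fixture(scope="session")
def small_atlas():
    """Cheaper 40^3 atlas for tests that only need valid structure."""
    return make_atlas_labels((40, 40, 40), (2.0, 2.0, 2.0), seed=3)


@pytest.fixture(scope="session")
def subject(atlas):
    """One phantom subject (labels only) derived from the reference atlas."""
    return make_phantom_subject(atlas, seed=1, with_intensities=False)


@pytest.fixture(scope="session")
def imaged_subject(atlas):
    """Phantom subject with all four synthesized sequences."""
    return make_phantom_subject(atlas, seed=2, with_intensities=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
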