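import numpy as np
import pytest

from scopesr import Crappifier, ImageStack, SpecimenSpec, generate_specimen


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_image(rng):
    """A seeded random 2-D image in [0, 1]."""
    return ImageStack(rng.random((96, 96), dtype=np.float64).astype(np.float32), "YX")


@pytest.fixture
def specimen():
    """A small deterministic synthetic micrograph."""
    return generate_specimen(SpecimenSpec(shape=(128, 128), n_spots=15, n_filaments=2, seed=7))


@pytest.fixture
def gaussian_crappifier():
    return Crappifier("additive_gaussian", intensity=0.1, clip=False)
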