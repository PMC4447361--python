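import numpy as np
import pytest

from darkbright.contrast import DogSpec, apply_operator, make_operator, to_equivalent_contrast
from darkbright.synthetic import NoiseSpec, generate_noise


@pytest.fixture(scope="session")
def op48():
    """The main-analysis operator: sigma_c = 4, surround ratio 2, 1 arcmin/px."""
    return make_operator(DogSpec(4.0, 8.0), pixel_size=1.0)


@pytest.fixture(scope="session")
def white_noise_maps(op48):
    """Equivalent-Weber contrast maps of a small white-noise ensemble."""
    pairs = generate_noise(NoiseSpec(noise_class=1, n_images=8, size=(256, 256), seed=3))
    return [
        to_equivalent_contrast(apply_operator(im, op48), op48.lookup_weber)
        for im, _ in pairs
    ]


@pytest.fixture(scope="session")
def skewed_noise_maps(op48):
    """Equivalent-Weber contrast maps of skewed 1/f^1.3 (class 3) noise."""
    pairs = generate_noise(NoiseSpec(noise_class=3, n_images=8, size=(256, 256), seed=3))
    return [
        to_equivalent_contrast(apply_operator(im, op48), op48.lookup_weber)
        for im, _ in pairs
    ]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
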