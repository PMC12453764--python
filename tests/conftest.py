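import numpy as np
import pytest

from dermapatch.synthdata import SynthConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small, clearly separable cohort shared across tests."""
    cfg = SynthConfig(n_images=40, image_size=(64, 64),
                      lesion_intensity_shift=0.3, seed=11)
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
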