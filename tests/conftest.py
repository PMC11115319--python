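import numpy as np
import pytest

import pointreadout as pr
from pointreadout.cores import GaborBankCore


@pytest.fixture(scope="session")
def tiny_core():
    """Small Gabor bank: 2 orientations x 1 frequency x 1 phase, 8x8 maps."""
    return GaborBankCore(n_orientations=2, frequencies=(0.15,), phases=(0.0,),
                         stride=8)


@pytest.fixture(scope="session")
def tiny_images():
    return pr.generate_images(12, size=64, seed=11).images


@pytest.fixture(scope="session")
def small_sessions():
    """One-session dataset small enough for quick fits, reused read-only."""
    return pr.assemble_area_dataset(
        n_sessions=1, images_per_session=300, neurons_per_session=8,
        n_test_images=40, test_repeats=20, seed=21)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
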