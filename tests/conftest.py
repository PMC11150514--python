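import numpy as np
import pytest

from mircomplete import SyntheticSpec, generate_planted_dataset, worked_example_fixture


@pytest.fixture
def example():
    """Tiny hand-checkable system shared across modules."""
    return worked_example_fixture()


@pytest.fixture(scope="session")
def planted_small():
    """A 30 x 20 noiseless planted dataset, cheap enough for CV loops."""
    return generate_planted_dataset(
        SyntheticSpec(nm=30, nd=20, latent_rank=3, density=0.3, noise_sd=0.0, seed=7)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
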