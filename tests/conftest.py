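import numpy as np
import pytest

from crossdti.data import SyntheticSpec, generate_synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_dataset():
    """A small noiseless planted-motif dataset with short sequences."""
    spec = SyntheticSpec(
        n_pairs=60,
        drug_length_range=(15, 30),
        protein_length_median=60.0,
        protein_length_sigma=0.2,
        protein_length_clip=(40, 90),
        seed=7,
    )
    return generate_synthetic(spec), spec
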