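import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", deadline=None, max_examples=50)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def tiny_dataset():
    from helpers import make_dataset

    return make_dataset(
        [[0, 1], [2, -1], [1, 0]],
        sexes=["male", "female", "unknown"],
        phenotypes=["case", "control", "missing"],
    )
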