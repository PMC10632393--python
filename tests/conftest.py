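import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def lesion_sample():
    """One default melanoma sample shared across read-only tests."""
    from melanopt import synthetic as syn

    return syn.generate_lesion_sample(syn.ImageGenConfig(seed=7), syn.MELANOMA)
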