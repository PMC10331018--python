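import numpy as np
import pytest

import modalmil as mm


@pytest.fixture(scope="session")
def small_cohort():
    """20-case phantom cohort at reduced resolution for fast tests."""
    cfg = mm.PhantomConfig(n_cases=20, image_size=48, slice_range=(2, 5), seed=7)
    return cfg, mm.generate_cohort(cfg)


@pytest.fixture(scope="session")
def tiny_extractor():
    return mm.ExtractorConfig(n_conv_layers=3, channels=(4, 6, 8),
                              embed_dim=16, input_size=16)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
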