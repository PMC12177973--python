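import numpy as np
import pytest

from slideprep.synthetic import SyntheticSpec, generate_sample


@pytest.fixture(scope="session")
def easy_sample():
    """One marker-frame slide with a single interior tissue blob."""
    return generate_sample(SyntheticSpec(seed=42))


@pytest.fixture(scope="session")
def hard_sample():
    """Slide whose tissue covers most of the marker frame."""
    return generate_sample(SyntheticSpec(seed=43, target_overlap=0.9))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
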