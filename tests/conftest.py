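import numpy as np
import pytest

from ettcascade.synthetic import SynthParams, simulate_exams


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_params():
    return SynthParams(image_h=128, image_w=128)


@pytest.fixture(scope="session")
def small_exams(small_params):
    """A handful of deterministic 128-px synthetic exams."""
    return simulate_exams(12, small_params, seed=3)
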