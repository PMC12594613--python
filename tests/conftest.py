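import numpy as np
import pytest

from darkdic import Constants, SyntheticTruth


@pytest.fixture
def constants() -> Constants:
    return Constants()


@pytest.fixture
def truth() -> SyntheticTruth:
    return SyntheticTruth(seed=7)


@pytest.fixture
def noise_free_truth() -> SyntheticTruth:
    return SyntheticTruth(seed=7).noise_free()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
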