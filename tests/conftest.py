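import numpy as np
import pytest

from isochron.synthetic import StudyDesign


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_design():
    """A down-scaled study design for fast pipeline/fit tests."""
    return StudyDesign(n_subjects=6, sets_per_tempo=1, intervals_per_set=40)
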