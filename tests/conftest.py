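import numpy as np
import pytest

import inflamark as im


@pytest.fixture(scope="session")
def default_cohort():
    """The study-sized cohort (214/214, 131 pre-diagnosis panels), seed 0."""
    return im.generate_cohort(im.default_config(seed=0))


@pytest.fixture(scope="session")
def default_markers(default_cohort):
    """Per-subject at-diagnosis marker table for the default cohort."""
    return im.marker_frame(default_cohort, "dx")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)

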