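import numpy as np
import pytest

from kinrecruit import build_cohort, sample_panel


@pytest.fixture
def rng():
    return np.random.default_rng(20140305)


@pytest.fixture(scope="session")
def small_cohort():
    """720 recruits in 120 families of 6 — the maximum-source-colony cohort."""
    return build_cohort(720, 6)


@pytest.fixture(scope="session")
def panel300():
    return sample_panel(300, 0.33, np.random.default_rng(11))
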