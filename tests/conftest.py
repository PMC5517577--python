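import numpy as np
import pytest

import dfcstates as d


@pytest.fixture(scope="session")
def small_sleep_cohort():
    """12 subjects, 12 regions, full-length sessions, two planted states."""
    return d.sleep_cohort(n_subjects=12, n_regions=12, seed=7)


@pytest.fixture(scope="session")
def small_windowed(small_sleep_cohort):
    return d.prepare_windows(
        small_sleep_cohort, d.WindowSpec(50), collapse=d.WAKE_SLEEP_COLLAPSE
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
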