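import numpy as np
import pytest

import omistrat as o


@pytest.fixture(scope="session")
def ref_cohort():
    """One reference-shaped cohort shared by read-only tests."""
    return o.reference_cohort(11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
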