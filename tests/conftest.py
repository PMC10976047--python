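import numpy as np
import pytest

from lesionloss.synthetic_data import PhantomSpec, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Six small-brain phantoms shared by the experiment-level tests."""
    spec = PhantomSpec.wmh_like(n_subjects=6, seed=3)
    return generate_cohort(spec)
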