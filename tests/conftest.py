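import numpy as np
import pytest

from welsh.cohort import generate_cohort, reference_config


@pytest.fixture(scope="session")
def ref_config():
    return reference_config(seed=0)


@pytest.fixture(scope="session")
def cohort_seed42(ref_config):
    """One full-size synthetic cohort at a fixed seed, shared across tests."""
    return generate_cohort(ref_config, seed=42)
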