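import numpy as np
import pytest

from dfcprint import build_parcellation, default_blueprint, simulate_eeg_cohort
from dfcprint.sensitivity import compute_phases


@pytest.fixture(scope="session")
def parc():
    return build_parcellation()


@pytest.fixture(scope="session")
def blueprint_matrix(parc):
    return default_blueprint(parc)


@pytest.fixture(scope="session")
def eeg_cohort():
    """Channel-level synthetic cohort shared across end-to-end suites."""
    return simulate_eeg_cohort(8, duration=120.0, sampling_rate=250.0,
                               band="beta", seed=3)


@pytest.fixture(scope="session")
def eeg_phases(eeg_cohort):
    return compute_phases(eeg_cohort)
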