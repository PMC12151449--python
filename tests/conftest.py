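import numpy as np
import pytest

from posmov import CohortSpec, sample_cohort
from posmov.experiment import cohort_frame_labels, truth_frame_labels


@pytest.fixture(scope="session")
def tiny_cohort():
    """Six short synthetic recordings with signals; shared across tests."""
    spec = CohortSpec(n_recordings=6, session_minutes=(3.0, 4.0), seed=11)
    return sample_cohort(spec, signals=True)


@pytest.fixture(scope="session")
def tiny_labels(tiny_cohort):
    return cohort_frame_labels(tiny_cohort)


@pytest.fixture(scope="session")
def tiny_truth(tiny_cohort):
    return truth_frame_labels(tiny_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
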