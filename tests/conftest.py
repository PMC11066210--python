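import numpy as np
import pytest

from swaylab import SimConfig, simulate_cohort
from swaylab.features import features_from_cohort


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_cohort():
    """The study-sized cohort: 34 subjects, calibrated condition scales."""
    return simulate_cohort(SimConfig(seed=0))


@pytest.fixture(scope="session")
def cohort_features(default_cohort):
    """Feature table for the placements the analysis ranks (7 sensors/subject)."""
    return features_from_cohort(
        default_cohort, placements=["lumbar", "ankle", "wrist", "arm"]
    )


@pytest.fixture(scope="session")
def lumbar_features(cohort_features):
    return cohort_features[cohort_features["placement"] == "lumbar"].reset_index(
        drop=True
    )
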