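import numpy as np
import pytest

from actidaily import (ScoringParams, SyntheticConfig, WristEpochSeries,
                       generate_cohort)
from actidaily.activity import train_reference_classifier
from actidaily.pipeline import RunConfig, _train_classifier


def make_wrist(counts, start="2017-09-12T23:00:00", offwrist=None, lux=None,
               pid="W"):
    counts = np.asarray(counts)
    if offwrist is None:
        offwrist = np.zeros(len(counts), bool)
    if lux is None:
        lux = np.zeros(len(counts))
    return WristEpochSeries(pid, np.datetime64(start), counts, offwrist, lux)


@pytest.fixture(scope="session")
def noisy_cohort():
    """Small rendered cohort with naps, arousals and non-wear gaps."""
    return generate_cohort(
        SyntheticConfig(n_participants=3, n_days=4, seed=7,
                        nap_prob=0.4, nonwear_rate=0.3)
    )


@pytest.fixture(scope="session")
def clean_cohort():
    """Rendered cohort with no naps, no gaps and no arousals."""
    return generate_cohort(
        SyntheticConfig(n_participants=3, n_days=4, seed=11,
                        nap_prob=0.0, nonwear_rate=0.0, arousals=False)
    )


@pytest.fixture(scope="session")
def reference_classifier():
    return _train_classifier(RunConfig(seed=5, classifier_train_minutes=4000))


@pytest.fixture
def wrist_builder():
    return make_wrist
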