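import numpy as np
import pytest

from alsonset import (
    StudyDesign,
    default_params,
    onset_table,
    score_table,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def default_cohort():
    """One seeded default cohort (longitudinal, endpoint)."""
    return simulate_cohort(StudyDesign(), default_params(), seed=1)


@pytest.fixture(scope="session")
def zero_noise_cohort():
    """Default cohort with every stochastic term switched off."""
    return simulate_cohort(StudyDesign(), default_params().without_noise(),
                           seed=1)


@pytest.fixture(scope="session")
def zero_noise_onsets(zero_noise_cohort):
    longitudinal, _ = zero_noise_cohort
    return onset_table(score_table(longitudinal))


@pytest.fixture(scope="session")
def replication_200():
    """The 200-cohort default replication used by several statistical checks."""
    from alsonset import replicate_study

    return replicate_study(n_cohorts=200, seed=1)
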