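import logging

import pytest

from seroscreen import (CohortConfig, call_seropositive, detect_cutoffs,
                        generate_cohort, score_matrix)

# constant-score-vector warnings from undetected antigens are expected noise
logging.getLogger("seroscreen.cutoffs").setLevel(logging.ERROR)


def small_config(**overrides) -> CohortConfig:
    """A reduced cohort (180 x 90, 40 symptoms) keeping the study's shape:
    spike rate set for ~10 expected autoantibodies per individual, planted
    antigens at a rate that keeps their group size above the margins."""
    params = dict(n_individuals=180, n_antigens=90, n_symptoms=40,
                  n_planted=3, spike_rate=10 / 90, planted_spike_rate=0.15,
                  seed=11)
    params.update(overrides)
    return CohortConfig(**params)


@pytest.fixture(scope="session")
def cohort():
    return generate_cohort(small_config())


@pytest.fixture(scope="session")
def scored(cohort):
    return score_matrix(cohort.mfi)


@pytest.fixture(scope="session")
def calls(cohort, scored):
    return call_seropositive(scored, detect_cutoffs(scored))
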