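import pytest

from palsy import CohortConfig, generate_cohort, labeled_feature_set

#: A small but fully populated five-class cohort (every class >= 10 rows so
#: stratified five-fold CV is always constructible).
SMALL_COUNTS = {"N": 24, "L_MI": 12, "R_MI": 10, "R_MO": 12, "R_S": 10}


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(CohortConfig(class_counts=SMALL_COUNTS, seed=7))


@pytest.fixture(scope="session")
def zero_noise_cohort():
    return generate_cohort(
        CohortConfig(class_counts=SMALL_COUNTS, noise_sd=0.0, seed=7)
    )


@pytest.fixture(scope="session")
def small_features(small_cohort):
    return labeled_feature_set(small_cohort)
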