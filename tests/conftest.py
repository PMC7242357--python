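import pytest

from oaprogress import preprocessing, synthetic


@pytest.fixture(scope="session")
def cohort_and_truth():
    """Small complete cohort with known latent classes."""
    spec = synthetic.CohortSpec(n_patients=100, seed=1)
    return synthetic.generate_cohort(spec)


@pytest.fixture(scope="session")
def cohort(cohort_and_truth):
    return cohort_and_truth[0]


@pytest.fixture(scope="session")
def truth(cohort_and_truth):
    return cohort_and_truth[1]


@pytest.fixture(scope="session")
def dataset(cohort):
    return preprocessing.build_dataset(cohort)
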