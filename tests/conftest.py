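import pytest
from hypothesis import settings

from bcpgenomics.genome import load_reference
from bcpgenomics.refsigs import load_reference_signatures
from bcpgenomics.simulate import CohortParams, simulate_cohort

settings.register_profile("suite", deadline=None, max_examples=50, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def genome():
    return load_reference()


@pytest.fixture(scope="session")
def sigref():
    return load_reference_signatures()


@pytest.fixture(scope="session")
def cohort_default():
    """Full cohort at the study's group sizes (35 BCP, 18 controls)."""
    return simulate_cohort(CohortParams(n_bcp=35, n_control=18, seed=20180806))


@pytest.fixture(scope="session")
def cohort_large_mutations():
    """Mutation catalogs at n=(1050,540) for frequency-recovery checks."""
    return simulate_cohort(
        CohortParams(n_bcp=1050, n_control=540, seed=11),
        stages={"clinical", "mutations"},
    )
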