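import pytest

from kinnet import fuse_cohort
from kinnet.synthetic import GeneratorConfig, example_household, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Six synthetic households exercising every fusion pattern."""
    return generate_cohort(GeneratorConfig(n_households=6, seed=11))


@pytest.fixture(scope="session")
def small_networks(small_cohort):
    return fuse_cohort(small_cohort.surveys())


@pytest.fixture(scope="session")
def study_cohort():
    """A cohort at the study's scale (36 households)."""
    return generate_cohort(GeneratorConfig(n_households=36, seed=5))


@pytest.fixture(scope="session")
def study_networks(study_cohort):
    return fuse_cohort(study_cohort.surveys())


@pytest.fixture(scope="session")
def fusion_example():
    """The father/husband/son three-reporter household."""
    return example_household()
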