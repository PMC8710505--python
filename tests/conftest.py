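import pytest

from htncea.io import load_packaged_arms
from htncea.synthetic import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def arms():
    """Packaged table transcriptions for the three strategy arms."""
    return load_packaged_arms()


@pytest.fixture()
def fresh_arms():
    return load_packaged_arms()


@pytest.fixture(scope="session")
def small_cohort():
    """A small deterministic synthetic trial (~300 patients)."""
    return generate_cohort(GeneratorConfig(seed=20240917, n_per_arm=100))


@pytest.fixture(scope="session")
def large_cohort():
    """~5,000-patient synthetic trial used for parameter recovery."""
    cfg = GeneratorConfig(seed=910613, n_per_arm=1700)
    return cfg, generate_cohort(cfg)
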