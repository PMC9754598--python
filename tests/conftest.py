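import warnings

import pytest

from carindex import CategoryLexicon, CohortSpec, generate_cohort
from carindex.synthetic_data import LinkBlock


@pytest.fixture(scope="session")
def lexicon():
    return CategoryLexicon.default()


@pytest.fixture(scope="session")
def noiseless_cohort():
    """50 cities, planted link with zero noise, fixed seed."""
    return generate_cohort(CohortSpec(n_cities=50, seed=42, link=LinkBlock(sigma=0.0)))


@pytest.fixture(scope="session")
def small_cohort():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_cohort(CohortSpec(n_cities=12, seed=7))
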