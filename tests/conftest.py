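from datetime import date

import pytest

from cd4rd import (
    apply_filters,
    cohort_from_frame,
    default_params,
    estimate_cd4_distribution,
    fit_global_rd,
    generate_cohort,
)

WINDOW = (date(2011, 8, 12), date(2013, 6, 30))
YEAR_2013 = (date(2013, 1, 1), date(2013, 12, 31))


@pytest.fixture(scope="session")
def default_cohort():
    """A 15,000-patient cohort from the default (350-cell regime) generator."""
    return cohort_from_frame(generate_cohort(default_params(15_000, seed=7)))


@pytest.fixture(scope="session")
def reg_sample(default_cohort):
    return apply_filters(default_cohort, *WINDOW)


@pytest.fixture(scope="session")
def fcd4_2013(default_cohort):
    return estimate_cd4_distribution(default_cohort, *YEAR_2013)


@pytest.fixture(scope="session")
def global_fit(reg_sample):
    return fit_global_rd(reg_sample, threshold=350)
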