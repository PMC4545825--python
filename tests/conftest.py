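import pytest

from whoish_cvd import (
    compare_cohort,
    default_aphri_params,
    generate_cohort,
    load_default_charts,
)


@pytest.fixture(scope="session")
def charts_pair():
    """Bundled synthetic (LI, HI) SEAR-D tables."""
    return load_default_charts()


@pytest.fixture(scope="session")
def cohort_1066():
    """Default-parameter synthetic cohort at the study size."""
    return generate_cohort(default_aphri_params(), 1066, seed=1).subjects


@pytest.fixture(scope="session")
def records_1066(cohort_1066, charts_pair):
    li, hi = charts_pair
    records, rejects = compare_cohort(cohort_1066, li, hi)
    assert not rejects
    return records
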