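import numpy as np
import pytest
from hypothesis import settings

from tracegtt.cohort import CohortDesign, sample_cohort, simulate_test
from tracegtt.mid import natural_abundance_matrix

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def na_matrix():
    return natural_abundance_matrix()


@pytest.fixture(scope="session")
def noiseless_design():
    return CohortDesign(
        n_per_group_per_sex=2, seed=7,
        noise_cv_glucose=0.0, noise_cv_enrichment=0.0, noise_cv_insulin=0.0,
    )


@pytest.fixture(scope="session")
def noiseless_mouse(noiseless_design):
    return sample_cohort(noiseless_design)[0]


@pytest.fixture(scope="session")
def noiseless_record(noiseless_mouse, noiseless_design):
    return simulate_test(noiseless_mouse, noiseless_design)


def enrichment_series(record, matrix):
    """Shared helper: corrected enrichment per glucose time point."""
    from tracegtt.mid import correct_mid, enrichment_from_mid

    return np.clip(
        [enrichment_from_mid(correct_mid(s, matrix)) for s in record.mid_raw],
        0.0, None,
    )
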