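import numpy as np
import pytest

from cesm_radiomics import (
    CohortConfig,
    extract_cohort_features,
    features_to_frame,
    generate_cohort,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A 30-lesion null cohort shared by read-only tests."""
    cfg = CohortConfig(n_lesions=30, seed=11)
    records, pairs = generate_cohort(cfg)
    return cfg, records, pairs


@pytest.fixture(scope="session")
def small_features(small_cohort):
    _, _, pairs = small_cohort
    return features_to_frame(extract_cohort_features(pairs))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260101)
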