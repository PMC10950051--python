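import numpy as np
import pytest

from adpanel.panel import AnalysisConfig, exclude_sparse_subjects, preprocess
from adpanel.synth import generate_cohort, preset


@pytest.fixture(scope="session")
def entire_cohort():
    """One seeded default synthetic cohort (raw, with sparse subjects)."""
    return generate_cohort(preset("entire_cohort", seed=0))


@pytest.fixture(scope="session")
def prepared(entire_cohort):
    """The same cohort after sparse-subject exclusion and preprocessing."""
    panel, labels = exclude_sparse_subjects(entire_cohort.panel, 0.5,
                                            entire_cohort.labels)
    return preprocess(panel), labels


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def tiny_config():
    """Small-budget analysis config for fast end-to-end runs."""
    return AnalysisConfig.scaled(seed=0, n_permutations=20, bo_iterations=5,
                                 cv_folds=5, max_cycles=20, max_splits_cap=12)
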