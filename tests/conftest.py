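import numpy as np
import pytest

from physdys import CohortSpec, ScoreConfig, generate_cohort, score_cohort


@pytest.fixture(scope="session")
def cohort_table():
    """Default-sized cohort (~3,300 subjects) with a true mortality effect
    of HR 1.4 per SD of latent dysregulation."""
    return generate_cohort(CohortSpec(seed=7))


@pytest.fixture(scope="session")
def scored_cohort(cohort_table):
    """The same cohort scored end to end (transform, reference, D_M, DI)."""
    scored, model, specs = score_cohort(cohort_table, ScoreConfig())
    return scored, model, specs


@pytest.fixture(scope="session")
def small_cohort():
    """A small cohort (~600 subjects) for fast structural tests."""
    return generate_cohort(CohortSpec(n_families=60, seed=11))
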