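import numpy as np
import pytest

from colipk.synth import (StudyDesign, generate_enriched_study,
                          generate_study, generate_true_params)


@pytest.fixture(scope="session")
def true_params():
    return generate_true_params()


@pytest.fixture(scope="session")
def small_study():
    """An 8-patient virtual cohort with urine and outcome annotations."""
    design = StudyDesign(n_patients=8, n_rich_patients=3, urine_subset_size=3,
                         seed=42)
    return generate_study(design)


@pytest.fixture(scope="session")
def enriched_small():
    """A 30-patient enriched-design study for estimation smoke tests."""
    return generate_enriched_study(n_patients=30, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
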