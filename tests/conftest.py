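import warnings

import numpy as np
import pytest

from facedna.cohort import make_face_template, simulate_cohort
from facedna.shape import symmetric_component

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def template():
    return make_face_template(60, seed=7)


@pytest.fixture(scope="session")
def small_cohort():
    """A compact cohort with every default effect injected."""
    return simulate_cohort(
        n_individuals=80, n_panel=40, n_snps=200, n_causal_snps=2,
        n_landmarks=60, seed=123,
    )


@pytest.fixture(scope="session")
def small_sym(small_cohort):
    return symmetric_component(small_cohort.faces, small_cohort.template)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
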