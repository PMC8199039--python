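import numpy as np
import pytest

from skiscore.reference import fit_reference
from skiscore.synthetic import generate_cohort
from skiscore.types import SyntheticParams


@pytest.fixture(scope="session")
def default_params():
    return SyntheticParams()


@pytest.fixture(scope="session")
def reference_cohort(default_params):
    """200 reference-like turns per cell in two (style, size) cells."""
    turns, truths = generate_cohort(
        default_params, 200,
        [("carving", "medium"), ("drifting", "medium")], seed=42)
    return turns, truths


@pytest.fixture(scope="session")
def reference_model(reference_cohort):
    turns, _ = reference_cohort
    return fit_reference(turns)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
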