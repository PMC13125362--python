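import numpy as np
import pytest

from pdscribe import drawgen


@pytest.fixture(scope="session")
def small_cohort():
    """In-memory 5+5 spiral-only cohort with a moderate PD effect."""
    return drawgen.synthesize_cohort(
        5, 5, tasks=("spiral",),
        pd_profile=drawgen.EFFECT_PROFILES["moderate"], seed=7)


@pytest.fixture(scope="session")
def multitask_cohort():
    """In-memory 3+3 cohort with all three tasks, smaller canvas for speed."""
    return drawgen.synthesize_cohort(
        3, 3, tasks=("spiral", "meander", "wave"),
        pd_profile=drawgen.EFFECT_PROFILES["strong"], seed=11, canvas=256,
        n_points=800)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
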