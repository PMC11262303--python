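import numpy as np
import pytest

from aecnet.bands import CANONICAL_BANDS
from aecnet.simulate import (
    DEFAULT_CONDITIONS,
    GenerativeParams,
    simulate_measure_table,
)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def alpha_band():
    return CANONICAL_BANDS["alpha"]


@pytest.fixture
def null_table():
    """Measure table simulated under the null (all slopes zero)."""
    gp = GenerativeParams(
        alpha_bar=np.log(0.3), beta_bar={},
        sigma_alpha=0.05, sigma_beta=0.05, sigma=0.05, n_subjects=30,
    )
    return simulate_measure_table(gp, DEFAULT_CONDITIONS, seed=7)


@pytest.fixture
def effect_table():
    """Measure table with a common slope of 0.1 on every stimulus."""
    gp = GenerativeParams(
        alpha_bar=np.log(0.3),
        beta_bar={c: 0.1 for c in DEFAULT_CONDITIONS[1:]},
        sigma_alpha=0.05, sigma_beta=0.05, sigma=0.05, n_subjects=30,
    )
    return simulate_measure_table(gp, DEFAULT_CONDITIONS, seed=11)
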