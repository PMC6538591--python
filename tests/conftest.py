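import sys
from pathlib import Path

import numpy as np
import pytest

import reghyp as rh

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable


@pytest.fixture(scope="session")
def names4():
    return ["b0", "b1", "b2", "b3"]


@pytest.fixture(scope="session")
def small_fit():
    """A reproducible 3-predictor fit with known sufficient statistics."""
    table = rh.generate_regression(
        rh.SimSpec(n=40, beta_true=(0.3, 0.6, 0.2, -0.1), seed=11)
    )
    return rh.fit_linear_model(table, "y ~ x1 + x2 + x3")


@pytest.fixture(scope="session")
def orthogonal_fit():
    """Two exactly orthogonal predictors, no intercept (diagonal X'X)."""
    table = rh.generate_exact_mle(
        [0.7, 0.03], 1.3, np.diag([5.0, 7.0]), n=20, seed=1
    )
    return rh.fit_linear_model(table, "y ~ x1 + x2 - 1")
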