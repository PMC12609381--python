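import numpy as np
import pytest

from ovogeom.epe_model import EPEParams


@pytest.fixture
def egg_params() -> EPEParams:
    """A mildly asymmetric egg shape used across modules."""
    return EPEParams(a=1.4, b=1.6, c1=0.10, c2=-0.05, c3=0.02)


@pytest.fixture
def sphere_params() -> EPEParams:
    return EPEParams(a=1.0, b=1.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def random_valid_params(rng, a_lo=0.5, a_hi=3.0, b_lo=0.5, b_hi=3.0, c_mag=0.2):
    """Rejection-sample a valid parameter set from the given box."""
    while True:
        p = EPEParams(rng.uniform(a_lo, a_hi), rng.uniform(b_lo, b_hi),
                      *rng.uniform(-c_mag, c_mag, 3))
        if p.is_valid():
            return p
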