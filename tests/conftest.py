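"""Shared fixtures: reference environment, leaf, and photochemical constants."""

import numpy as np
import pytest

from cb6f.light_reactions import PhotochemicalConstants
from cb6f.solver import LeafParameters
from cb6f.stoichiometry import (
    CouplingEfficiencies,
    Environment,
    RubiscoKinetics,
    co2_compensation,
    eta,
    rubisco_specificity,
)


@pytest.fixture(scope="session")
def env():
    """Reference simulation conditions: C=200 µbar, O=209 mbar, 25 °C."""
    return Environment(c=200.0, o=209.0)


@pytest.fixture(scope="session")
def kin():
    return RubiscoKinetics()


@pytest.fixture(scope="session")
def k():
    return PhotochemicalConstants()


@pytest.fixture(scope="session")
def leaf():
    """Reference leaf (α=0.85 split 0.41/0.44, V_max 350/100, R_d=1)."""
    return LeafParameters()


@pytest.fixture(scope="session")
def coupling():
    return CouplingEfficiencies()


@pytest.fixture(scope="session")
def gamma_star(kin):
    return co2_compensation(rubisco_specificity(kin), 209.0)


@pytest.fixture(scope="session")
def eta_ref(coupling, gamma_star):
    """PS I : PS II flux ratio at the reference conditions (≈1.0344)."""
    return eta(coupling, gamma_star, 200.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
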