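"""Shared fixtures: reference morphologies, models and parameter sets.

Session-scoped so the numba kernel is compiled once and morphology
generation is not repeated per test.
"""

import numpy as np
import pytest

from ca3burst.biophysics import GMAX_NAMES, ParameterSet
from ca3burst.celltypes import athorny_reference, thorny_reference
from ca3burst.morphology import (
    Morphology,
    Section,
    athorny_spec,
    generate_reduced_morphology,
    thorny_spec,
)
from ca3burst.simulator import discretize


@pytest.fixture(scope="session")
def passive_params():
    """Leak-only parameter set (analytic oracles)."""
    gmax = {n: 0.0 for n in GMAX_NAMES}
    gmax["gbar_leak_somatodendritic"] = 5e-5
    gmax["gbar_leak_axonal"] = 5e-5
    return ParameterSet(gmax=gmax, el_somatodendritic=-70.0, el_axonal=-70.0)


@pytest.fixture(scope="session")
def soma_only_model():
    """Single cylindrical soma, one compartment."""
    m = Morphology([Section(1, None, "soma", 20.0, 20.0, 20.0)])
    return discretize(m, 25.0)


@pytest.fixture(scope="session")
def thorny_morph():
    return generate_reduced_morphology(thorny_spec())


@pytest.fixture(scope="session")
def athorny_morph():
    return generate_reduced_morphology(athorny_spec())


@pytest.fixture(scope="session")
def thorny_model(thorny_morph):
    return discretize(thorny_morph, 25.0)


@pytest.fixture(scope="session")
def athorny_model(athorny_morph):
    return discretize(athorny_morph, 25.0)


@pytest.fixture(scope="session")
def thorny_params():
    return thorny_reference()


@pytest.fixture(scope="session")
def athorny_params():
    return athorny_reference()
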