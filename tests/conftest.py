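"""Shared fixtures: nominal model objects and expensive session-scoped runs."""

import numpy as np
import pytest

import dopasim as ds
from dopasim.experiments import forced_limit_cycle, nominal_eda_reference


@pytest.fixture(scope="session")
def params():
    return ds.ReducedParams()


@pytest.fixture(scope="session")
def calib():
    return ds.AutoreceptorCalibration()


@pytest.fixture(scope="session")
def nominal_equilibrium(params, calib):
    return ds.find_equilibrium(params, ds.FrozenForcing(), calib)


@pytest.fixture(scope="session")
def eda_reference(params, calib):
    return nominal_eda_reference(params, calib)


@pytest.fixture(scope="session")
def limit_cycle(params, calib):
    """Post-burn-in 24-h circadian limit cycle of the drug-free model."""
    return forced_limit_cycle(params, calib)


@pytest.fixture(scope="session")
def forced_two_days(params, calib):
    """Two post-burn-in days of the drug-free forced model, finely sampled."""
    model = ds.ReducedModel()
    return ds.run_protocol(model, None, days=2, burn_in_hours=240.0)
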