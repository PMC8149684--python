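"""Shared fixtures.

Steady solves are the expensive primitive, so the tuned upper-body
resistance, a nominal steady solution and a fitted nominal patient are
session-scoped and shared across modules.
"""

import numpy as np
import pytest

from lumpedheart.estimation import (fit_patient, nominal_healthy_record,
                                    seed_qmpv, tune_upper_body)
from lumpedheart.network import simulate_to_steady
from lumpedheart.records import CirculationParams
from lumpedheart.valves import build_patient_valves


@pytest.fixture(scope="session")
def tuned_r_ub() -> float:
    return tune_upper_body(CirculationParams())


@pytest.fixture(scope="session")
def nominal_record():
    return nominal_healthy_record()


@pytest.fixture(scope="session")
def nominal_steady(nominal_record, tuned_r_ub):
    """(params, valves, waves, info) for the healthy baseline at its
    closed-form Q_MPV seed and the tuned upper-body split."""
    params = CirculationParams(R_ub=tuned_r_ub, Q_MPV=seed_qmpv(nominal_record))
    valves = build_patient_valves(nominal_record)
    waves, info = simulate_to_steady(params, valves, nominal_record)
    return params, valves, waves, info


@pytest.fixture(scope="session")
def fitted_nominal(nominal_record, tuned_r_ub):
    return fit_patient(nominal_record, r_ub=tuned_r_ub)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
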