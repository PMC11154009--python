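import warnings

import numpy as np
import pytest

from mpndyn import (
    DEFAULT_PARAMETERS,
    DISEASE_ONSET_STATE,
    DAYS_PER_YEAR,
    ScenarioSpec,
    find_steady_states,
    run_scenario,
    simulate,
)

# LSODA emits convergence chatter while screening extreme parameter
# combinations; the solver status is checked explicitly everywhere.
warnings.filterwarnings("ignore", message="lsoda:", category=UserWarning)


@pytest.fixture(scope="session")
def params():
    return DEFAULT_PARAMETERS


@pytest.fixture(scope="session")
def steady_records(params):
    return find_steady_states(params)


@pytest.fixture(scope="session")
def feasible_states(steady_records):
    return [r for r in steady_records if r.feasible]


@pytest.fixture(scope="session")
def untreated_30y(params):
    """Untreated 30-year disease-onset run (weekly samples)."""
    return simulate(DISEASE_ONSET_STATE, params, 30 * DAYS_PER_YEAR)


@pytest.fixture(scope="session")
def scenario_b(params):
    """Stem-cell-only treatment scenario (s_y0 x6 after 30 untreated years)."""
    return run_scenario(ScenarioSpec(scenario="b", post_treatment_years=20.0), params)
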