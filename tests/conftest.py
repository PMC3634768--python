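"""Shared fixtures: synthesized gains and packaged-scenario runs.

Session-scoped because gain synthesis and closed-loop integration are the
expensive steps and several test modules interrogate the same trajectories.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from tremorloop import (
    make_case1,
    make_case2,
    make_recovery_suite,
    run_scenario,
    synthesize_gains,
)
from tremorloop.fixtures import case_bounds, recovery_bounds

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

RECOVERY_SEED = 7
N_RECOVERY = 20


@pytest.fixture(scope="session")
def recovery_gains():
    return synthesize_gains(recovery_bounds())


@pytest.fixture(scope="session")
def case_gains():
    return synthesize_gains(case_bounds())


@pytest.fixture(scope="session")
def recovery_runs(recovery_gains):
    """The randomized amplitude-recovery ensemble: list of (scenario, trajectory)."""
    suite = make_recovery_suite(seed=RECOVERY_SEED, n=N_RECOVERY)
    return [(s, run_scenario(s, gains=recovery_gains)) for s in suite]


@pytest.fixture(scope="session")
def case1_run(case_gains):
    scenario = make_case1()
    return scenario, run_scenario(scenario, gains=case_gains)


@pytest.fixture(scope="session")
def case2_run(case_gains):
    scenario = make_case2()
    return scenario, run_scenario(scenario, gains=case_gains)
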