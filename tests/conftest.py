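import numpy as np
import pytest

import priorweight as pw
from priorweight.hierarchical import HierarchicalData


@pytest.fixture(scope="session")
def default_design():
    return pw.TaskDesign()


@pytest.fixture(scope="session")
def small_design():
    """A shortened task (2 blocks of 15 trials, 5 estimation each) used to
    keep simulation-heavy calibration tests fast."""
    return pw.TaskDesign(n_blocks=2, trials_per_block=15, basic_per_block=10,
                         estimation_per_block=5)


def make_pd_sessions(params_list, seed0=1000, discretize=True, design=None):
    """Placebo + atomoxetine session pair per observer."""
    sessions = []
    for i, p in enumerate(params_list):
        for j, cond in enumerate(("placebo", "atomoxetine")):
            sessions.append(pw.simulate_session(
                p, design, cond, seed=seed0 + 2 * i + j,
                participant_id=f"PD{i:02d}", group="PD",
                session_order=j + 1, discretize=discretize,
            ))
    return sessions


@pytest.fixture(scope="session")
def known_observers():
    hyper = pw.GroupHyperParams()
    return pw.draw_observer_params(hyper, 5, seed=21)


@pytest.fixture(scope="session")
def pd_fixture(known_observers):
    """Five crossover observers with continuous responses, plus the
    hierarchical data view — the shared fixture for sampler tests."""
    sessions = make_pd_sessions(known_observers, seed0=500, discretize=False)
    return sessions, HierarchicalData.from_sessions(sessions)


@pytest.fixture(scope="session")
def small_cohort():
    sessions, covariates = pw.simulate_cohort(seed=99)
    return sessions, covariates
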