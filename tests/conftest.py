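import datetime as dt

import numpy as np
import pandas as pd
import pytest

import waitlist_msm as wm
from waitlist_msm.event_history import TRANSITION_TABLE_COLUMNS


@pytest.fixture(scope="session")
def space():
    return wm.build_state_space()


@pytest.fixture(scope="session")
def structure(space):
    return wm.build_transition_structure(space)


@pytest.fixture(scope="session")
def val_scenario():
    """Moderate estimator-validation cohort shared across tests."""
    return wm.validation_scenario(n_subjects=800, seed=20240, censoring_rate=2e-4)


@pytest.fixture(scope="session")
def val_records(val_scenario):
    return wm.simulate_cohort(val_scenario)


@pytest.fixture(scope="session")
def val_table(val_records, structure):
    return wm.prepare_transition_table(val_records, structure)


@pytest.fixture(scope="session")
def val_fit(val_table, structure):
    return wm.fit_multistate(val_table, structure)


@pytest.fixture(scope="session")
def val_truth(val_scenario):
    def truth(s, t):
        return wm.true_transition_probability(val_scenario.intensities, s, t)

    return truth


def make_record(
    subject_id,
    initial_cpra=0.0,
    initial_status=wm.ActivityStatus.ACTIVE,
    updates=(),
    terminal_day=None,
    terminal_state=None,
    censor_day=None,
    listing_date=dt.date(2010, 1, 1),
    **kwargs,
):
    return wm.RegistrantRecord(
        subject_id=subject_id,
        listing_date=listing_date,
        age_at_listing=kwargs.pop("age_at_listing", 50.0),
        initial_cpra=initial_cpra,
        initial_status=initial_status,
        updates=list(updates),
        terminal_day=terminal_day,
        terminal_state=terminal_state,
        censor_day=censor_day,
        **kwargs,
    )


@pytest.fixture
def record_factory():
    return make_record


def table_from_paths(paths, structure):
    """Long-format table straight from continuous-time paths (test oracle
    route that bypasses the day-grid record encoding)."""
    space = structure.space
    rows = []
    for p in paths:
        states = (p.initial_state,) + p.jump_states
        times = (0.0,) + p.jump_times
        for k, (st, t0) in enumerate(zip(states, times)):
            if space.is_absorbing(st):
                break
            t1 = times[k + 1] if k + 1 < len(times) else p.end_time
            dest = states[k + 1] if k + 1 < len(states) else None
            for to in structure.destinations(st):
                rows.append(
                    (
                        p.subject_id,
                        st,
                        to,
                        structure.transition_id(st, to),
                        t0,
                        t1,
                        int(dest == to),
                    )
                )
    return pd.DataFrame(rows, columns=TRANSITION_TABLE_COLUMNS)


@pytest.fixture(scope="session")
def grid_365():
    return np.array([365.0])
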