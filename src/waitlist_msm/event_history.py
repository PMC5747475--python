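"""From per-registrant records to state trajectories and long-format data.

A :class:`RegistrantRecord` holds what a registry extract provides for one
candidate: listing date, eligibility fields, initial CPRA/activity status,
dated CPRA/status updates, and either a terminal outcome or a censoring day.
This module converts such records into chains of :class:`StateInterval` on
the 16-state space, applies a censoring scheme (administrative horizon and/or
censoring at an allocation-policy change date), and expands intervals into
the stacked long format used for estimation: one at-risk row per allowed
transition leaving the occupied state, with an event indicator on the
realized transition.

Time is measured in days since listing (clock-forward): the Markov model is
time-inhomogeneous in elapsed time from the listing origin.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .state_space import (
    ActivityStatus,
    StateSpace,
    TransitionStructure,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Update",
    "RegistrantRecord",
    "CensoringScheme",
    "StateInterval",
    "MalformedRecordError",
    "filter_cohort",
    "trajectory_from_record",
    "apply_censoring",
    "prepare_transition_table",
    "TRANSITION_TABLE_COLUMNS",
]

COVARIATE_KEYS = ("age_group", "gender", "abo", "race", "esrd_diagnosis")

TRANSITION_TABLE_COLUMNS = [
    "subject_id",
    "from_index",
    "to_index",
    "transition_id",
    "t_start",
    "t_stop",
    "status",
]


class MalformedRecordError(ValueError):
    """A registrant record violates its internal time ordering."""


@dataclass(frozen=True)
class Update:
    """A dated change: CPRA and/or activity status on a day since listing."""

    day: float
    cpra: float | None = None
    status: ActivityStatus | None = None


@dataclass
class RegistrantRecord:
    subject_id: str
    listing_date: dt.date
    age_at_listing: float
    initial_cpra: float
    initial_status: ActivityStatus
    first_time: bool = True
    multi_organ: bool = False
    covariates: dict[str, str] = field(default_factory=dict)
    updates: list[Update] = field(default_factory=list)
    terminal_day: float | None = None
    terminal_state: int | None = None  # absorbing state index 13-16
    censor_day: float | None = None

    def __post_init__(self) -> None:
        days = [u.day for u in self.updates]
        if any(b < a for a, b in zip(days, days[1:])):
            raise MalformedRecordError(
                f"{self.subject_id}: update days must be non-decreasing"
            )
        if self.terminal_day is not None and self.censor_day is not None:
            raise MalformedRecordError(
                f"{self.subject_id}: terminal and censor are mutually exclusive"
            )
        end = self.terminal_day if self.terminal_day is not None else self.censor_day
        if end is not None and days and end < days[-1]:
            raise MalformedRecordError(
                f"{self.subject_id}: end day {end} precedes an update day"
            )


@dataclass(frozen=True)
class CensoringScheme:
    """Right-censoring rules applied on top of what the record carries.

    ``censor_at_policy`` truncates every trajectory at the allocation-policy
    change date (converted to days since that subject's listing), turning
    later terminal events into censorings — this isolates the pre-policy era.
    With censoring lifted (``censor_at_policy=False``) the policy date is
    ignored and only ``admin_horizon_day`` applies.
    """

    policy_date: dt.date | None = None
    censor_at_policy: bool = False
    admin_horizon_day: int | None = None

    def __post_init__(self) -> None:
        if self.censor_at_policy and self.policy_date is None:
            raise ValueError("censor_at_policy requires a policy_date")


@dataclass(frozen=True)
class StateInterval:
    """Occupancy of one transient state over [start_day, end_day)."""

    state_index: int
    start_day: float
    end_day: float
    end_state: int | None  # destination state index, None if censored

    @property
    def censored(self) -> bool:
        return self.end_state is None


def filter_cohort(
    records: Iterable[RegistrantRecord],
    window_start: dt.date,
    window_end: dt.date,
) -> list[RegistrantRecord]:
    """Apply cohort-eligibility rules.

    Retains adult (age > 18) first-time kidney-only registrants listed within
    [window_start, window_end].  Per-rule exclusion counts go to the log.
    """
    kept: list[RegistrantRecord] = []
    excluded = {"window": 0, "age": 0, "not_first_time": 0, "multi_organ": 0}
    for rec in records:
        if not (window_start <= rec.listing_date <= window_end):
            excluded["window"] += 1
        elif rec.age_at_listing <= 18:
            excluded["age"] += 1
        elif not rec.first_time:
            excluded["not_first_time"] += 1
        elif rec.multi_organ:
            excluded["multi_organ"] += 1
        else:
            kept.append(rec)
    logger.info(
        "cohort filter: kept %d; excluded %s",
        len(kept),
        ", ".join(f"{k}={v}" for k, v in excluded.items()),
    )
    return kept


def trajectory_from_record(
    record: RegistrantRecord, space: StateSpace
) -> list[StateInterval]:
    """Resolve a record into its chain of transient-state intervals.

    The entry state comes from (initial_cpra, initial_status) at day 0.
    Updates that leave the occupied state unchanged (e.g. a CPRA move within
    one category) create no boundary; same-day updates merge into a single
    transition to the combined new state.  Zero-length intervals are dropped
    with a warning.  A terminal event on day 0 is shifted to day 0.5 so the
    subject contributes at-risk time.
    """
    cpra = record.initial_cpra
    status = record.initial_status
    current_state = space.transient_index(cpra, status)

    end_day = record.terminal_day if record.terminal_day is not None else record.censor_day
    if record.terminal_day is not None:
        for u in record.updates:
            if u.day > record.terminal_day:
                raise MalformedRecordError(
                    f"{record.subject_id}: update after terminal day"
                )
    if end_day is not None and end_day == 0 and record.terminal_day is not None:
        end_day = 0.5
        logger.warning(
            "%s: terminal event on listing day shifted to day 0.5", record.subject_id
        )

    # collapse updates day by day into state change-points
    change_points: list[tuple[float, int]] = [(0.0, current_state)]
    day_groups: dict[float, list[Update]] = {}
    for u in record.updates:
        day_groups.setdefault(u.day, []).append(u)
    for day in sorted(day_groups):
        for u in day_groups[day]:
            if u.cpra is not None:
                cpra = u.cpra
            if u.status is not None:
                status = u.status
        new_state = space.transient_index(cpra, status)
        if new_state != change_points[-1][1]:
            change_points.append((day, new_state))

    intervals: list[StateInterval] = []
    for (day, state), (next_day, next_state) in zip(change_points, change_points[1:]):
        if next_day == day:
            # a day-0 state change supersedes the nominal entry state
            logger.warning(
                "%s: zero-length interval in state %d at day %g dropped",
                record.subject_id,
                state,
                day,
            )
            continue
        intervals.append(StateInterval(state, day, next_day, next_state))

    last_day, last_state = change_points[-1]
    if end_day is not None:
        if end_day > last_day:
            dest = record.terminal_state if record.terminal_day is not None else None
            intervals.append(StateInterval(last_state, last_day, end_day, dest))
        elif record.terminal_day is not None:
            logger.warning(
                "%s: zero-length terminal interval dropped", record.subject_id
            )
    return intervals


def apply_censoring(
    trajectory: Sequence[StateInterval],
    record: RegistrantRecord,
    scheme: CensoringScheme,
) -> list[StateInterval]:
    """Truncate a trajectory per the censoring scheme.  Idempotent.

    Returns an empty list when the policy boundary precedes listing (the
    subject contributes nothing to a policy-censored analysis).
    """
    boundary: float | None = None
    if scheme.censor_at_policy and scheme.policy_date is not None:
        boundary = float((scheme.policy_date - record.listing_date).days)
        if boundary <= 0:
            return []
    if scheme.admin_horizon_day is not None:
        h = float(scheme.admin_horizon_day)
        boundary = h if boundary is None else min(boundary, h)
    if boundary is None:
        return list(trajectory)

    out: list[StateInterval] = []
    for iv in trajectory:
        if iv.start_day >= boundary:
            break
        if iv.end_day <= boundary:
            out.append(iv)
        else:
            out.append(replace(iv, end_day=boundary, end_state=None))
            break
    return out


def prepare_transition_table(
    records: Iterable[RegistrantRecord],
    structure: TransitionStructure,
    scheme: CensoringScheme | None = None,
) -> pd.DataFrame:
    """Expand trajectories into the stacked long format for estimation.

    Each state interval yields one row per allowed transition out of that
    state; ``status`` is 1 only on the realized transition.  Rows are ordered
    by (subject_id, t_start, transition_id) and carry the record covariates.
    """
    space = structure.space
    rows: list[tuple] = []
    for rec in records:
        traj = trajectory_from_record(rec, space)
        if scheme is not None:
            traj = apply_censoring(traj, rec, scheme)
        cov = tuple(rec.covariates.get(k, "") for k in COVARIATE_KEYS)
        for iv in traj:
            if iv.end_state is not None and not structure.is_allowed(
                iv.state_index, iv.end_state
            ):
                raise RuntimeError(
                    f"{rec.subject_id}: realized transition "
                    f"{iv.state_index}->{iv.end_state} not in structure"
                )
            for to_index in structure.destinations(iv.state_index):
                tid = structure.transition_id(iv.state_index, to_index)
                event = int(iv.end_state == to_index)
                rows.append(
                    (
                        rec.subject_id,
                        iv.state_index,
                        to_index,
                        tid,
                        iv.start_day,
                        iv.end_day,
                        event,
                    )
                    + cov
                )
    table = pd.DataFrame(
        rows, columns=TRANSITION_TABLE_COLUMNS + list(COVARIATE_KEYS)
    )
    table.sort_values(
        ["subject_id", "t_start", "transition_id"], inplace=True, kind="mergesort"
    )
    table.reset_index(drop=True, inplace=True)
    return table


def realized_transition_counts(
    records: Iterable[RegistrantRecord],
    structure: TransitionStructure,
    scheme: CensoringScheme | None = None,
) -> Mapping[int, int]:
    """Event count per transition id, straight from the trajectories."""
    counts: dict[int, int] = {}
    space = structure.space
    for rec in records:
        traj = trajectory_from_record(rec, space)
        if scheme is not None:
            traj = apply_censoring(traj, rec, scheme)
        for iv in traj:
            if iv.end_state is not None:
                tid = structure.transition_id(iv.state_index, iv.end_state)
                counts[tid] = counts.get(tid, 0) + 1
    return counts
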