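"""Delimited-text readers and writers for every pipeline artifact.

Formats (all UTF-8 CSV with header rows):

* registrants: one row per subject; ``updates`` encodes dated changes as
  semicolon-separated ``day:cpra:status`` triples (empty field = unchanged).
* states / transitions structure exports.
* transitions table: the stacked long format.
* hazards: ``transition_id,time,dA,var_dA`` jump lists.
* probabilities: ``origin_s,time,from_index,to_index,estimate,se,lower,upper``.
"""

from __future__ import annotations

import datetime as dt
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .event_history import COVARIATE_KEYS, RegistrantRecord, Update
from .np_estimation import (
    CumulativeHazardSet,
    TransitionProbabilityTrajectory,
    confidence_interval,
)
from .state_space import ActivityStatus, N_STATES, StateSpace, TransitionStructure

__all__ = [
    "write_registrants",
    "read_registrants",
    "write_state_table",
    "write_transition_structure",
    "write_transition_table",
    "read_transition_table",
    "write_hazards",
    "write_probabilities",
    "write_manifest",
]


def _encode_updates(updates: list[Update]) -> str:
    parts = []
    for u in updates:
        cpra = "" if u.cpra is None else f"{u.cpra:g}"
        status = "" if u.status is None else u.status.value
        parts.append(f"{u.day:g}:{cpra}:{status}")
    return ";".join(parts)


def _decode_updates(text: str) -> list[Update]:
    if not text:
        return []
    updates = []
    for part in text.split(";"):
        day, cpra, status = part.split(":")
        updates.append(
            Update(
                day=float(day),
                cpra=float(cpra) if cpra else None,
                status=ActivityStatus(status) if status else None,
            )
        )
    return updates


def registrants_to_frame(records: list[RegistrantRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "subject_id": r.subject_id,
            "listing_date": r.listing_date.isoformat(),
            "age_at_listing": float(r.age_at_listing),
            "first_time": int(r.first_time),
            "multi_organ": int(r.multi_organ),
            **{k: r.covariates.get(k, "") for k in COVARIATE_KEYS},
            "initial_cpra": float(r.initial_cpra),
            "initial_status": r.initial_status.value,
            "updates": _encode_updates(r.updates),
            "terminal_day": "" if r.terminal_day is None else f"{r.terminal_day:g}",
            "terminal_state": "" if r.terminal_state is None else r.terminal_state,
            "censor_day": "" if r.censor_day is None else f"{r.censor_day:g}",
        }
        rows.append(row)
    return pd.DataFrame(rows)


def write_registrants(records: list[RegistrantRecord], path: str | Path) -> None:
    registrants_to_frame(records).to_csv(path, index=False)


def read_registrants(
    path: str | Path, missing_cpra_default: float = 0.0
) -> list[RegistrantRecord]:
    """Read a registrants file.

    A blank initial CPRA is imputed as ``missing_cpra_default`` (registry
    extracts occasionally lack the listing value) and logged.
    """
    import logging

    logger = logging.getLogger(__name__)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    records = []
    for _, row in df.iterrows():
        if not row["initial_cpra"]:
            logger.warning(
                "%s: missing CPRA at listing imputed as %g",
                row["subject_id"],
                missing_cpra_default,
            )
            row = row.copy()
            row["initial_cpra"] = str(missing_cpra_default)
        records.append(
            RegistrantRecord(
                subject_id=row["subject_id"],
                listing_date=dt.date.fromisoformat(row["listing_date"]),
                age_at_listing=float(row["age_at_listing"]),
                first_time=bool(int(row["first_time"])),
                multi_organ=bool(int(row["multi_organ"])),
                covariates={k: row[k] for k in COVARIATE_KEYS if row.get(k, "")},
                initial_cpra=float(row["initial_cpra"]),
                initial_status=ActivityStatus(row["initial_status"]),
                updates=_decode_updates(row["updates"]),
                terminal_day=float(row["terminal_day"]) if row["terminal_day"] else None,
                terminal_state=(
                    int(row["terminal_state"]) if row["terminal_state"] else None
                ),
                censor_day=float(row["censor_day"]) if row["censor_day"] else None,
            )
        )
    return records


def write_state_table(space: StateSpace, path: str | Path) -> None:
    rows = [
        {
            "state_index": st.index,
            "kind": "transient",
            "cpra_label": st.cpra.label,
            "status": st.status.value,
        }
        for st in space.transient
    ] + [
        {"state_index": st.index, "kind": "absorbing", "cpra_label": st.label, "status": ""}
        for st in space.absorbing
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_transition_structure(structure: TransitionStructure, path: str | Path) -> None:
    pd.DataFrame(
        [
            {"transition_id": i, "from_index": f, "to_index": t}
            for f, t, i in structure.entries
        ]
    ).to_csv(path, index=False)


def write_transition_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_transition_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path,
        dtype={"subject_id": str},
        keep_default_na=False,
        na_values=[],
    )


def write_hazards(hazards: CumulativeHazardSet, path: str | Path) -> None:
    hazards.to_frame().to_csv(path, index=False)


def probabilities_to_frame(
    trajectory: TransitionProbabilityTrajectory,
    times: np.ndarray | None = None,
    level: float = 0.95,
    ci_method: str = "linear",
) -> pd.DataFrame:
    lower, upper = confidence_interval(trajectory, level=level, method=ci_method)
    grid = trajectory.times if times is None else np.atleast_1d(times)
    idx = np.searchsorted(trajectory.times, grid, side="right") - 1
    rows = []
    for g, t in zip(idx, grid):
        for i in range(N_STATES):
            for j in range(N_STATES):
                rows.append(
                    (
                        trajectory.origin,
                        t,
                        i + 1,
                        j + 1,
                        trajectory.probabilities[g, i, j],
                        float(np.sqrt(trajectory.variance[g, i, j])),
                        lower[g, i, j],
                        upper[g, i, j],
                    )
                )
    return pd.DataFrame(
        rows,
        columns=[
            "origin_s",
            "time",
            "from_index",
            "to_index",
            "estimate",
            "se",
            "lower",
            "upper",
        ],
    )


def write_probabilities(
    trajectory: TransitionProbabilityTrajectory,
    path: str | Path,
    times: np.ndarray | None = None,
    level: float = 0.95,
    ci_method: str = "linear",
) -> None:
    probabilities_to_frame(trajectory, times=times, level=level, ci_method=ci_method).to_csv(
        path, index=False, float_format="%.10g"
    )


def write_manifest(path: str | Path, **entries) -> None:
    """Machine-readable run manifest (inputs, seed, versions)."""
    from . import __version__

    payload = {"package": "waitlist-msm", "version": __version__, **entries}
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
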