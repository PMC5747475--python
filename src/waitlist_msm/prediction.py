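"""Probability queries on a fitted multi-state model.

These are the clinical products of the model: one-year cross-sections of
transition probabilities from each initial state, cumulative death curves
stratified by initial activity status, dynamic predictions of absorbing
outcomes from a state occupied at a later time, and two-cohort comparisons
(e.g. before vs after an allocation-policy change) read off confidence-band
overlap.

Under the Markov assumption, conditioning on a candidate's history up to a
prediction time s reduces to conditioning on the state occupied at s, so a
dynamic prediction is simply a row of P(s, t) restricted to absorbing
columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .np_estimation import (
    MultiStateFit,
    TransitionProbabilityTrajectory,
    aalen_johansen,
    confidence_interval,
)
from .state_space import AbsorbingState, N_STATES, N_TRANSIENT

__all__ = [
    "CrossSection",
    "CohortComparison",
    "state_probabilities",
    "dynamic_prediction",
    "death_curves",
    "compare_cohorts",
]


@dataclass(frozen=True)
class CrossSection:
    """One row of P(s, t): where a candidate starting in ``from_state`` at
    time s is expected to be at time t."""

    from_state: int
    origin: float
    horizon: float
    probabilities: np.ndarray  # (16,)
    standard_errors: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float

    def to_frame(self, space) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "initial_state": self.from_state,
                "origin_day": self.origin,
                "horizon_day": self.horizon,
                "to_index": np.arange(1, N_STATES + 1),
                "outcome": [space.state_label(i) for i in range(1, N_STATES + 1)],
                "estimate": self.probabilities,
                "se": self.standard_errors,
                "lower": self.lower,
                "upper": self.upper,
            }
        )


@dataclass(frozen=True)
class CohortComparison:
    """Paired estimates of one absorbing outcome in two cohorts."""

    from_state: int
    target: int
    horizon: float
    estimate_a: float
    estimate_b: float
    ci_a: tuple[float, float]
    ci_b: tuple[float, float]
    level: float

    @property
    def difference(self) -> float:
        return self.estimate_b - self.estimate_a

    @property
    def ci_overlap(self) -> bool:
        return self.ci_a[0] <= self.ci_b[1] and self.ci_b[0] <= self.ci_a[1]


def _row_cross_section(
    trajectory: TransitionProbabilityTrajectory,
    from_state: int,
    t: float,
    level: float,
    method: str,
) -> CrossSection:
    lower, upper = confidence_interval(trajectory, level=level, method=method)
    idx = int(np.searchsorted(trajectory.times, t, side="right")) - 1
    r = from_state - 1
    return CrossSection(
        from_state=from_state,
        origin=trajectory.origin,
        horizon=t,
        probabilities=trajectory.probabilities[idx, r].copy(),
        standard_errors=np.sqrt(trajectory.variance[idx, r]),
        lower=lower[idx, r].copy(),
        upper=upper[idx, r].copy(),
        level=level,
    )


def state_probabilities(
    fit: MultiStateFit,
    from_state: int,
    s: float,
    t: float,
    level: float = 0.95,
    ci_method: str = "linear",
) -> CrossSection:
    """Row ``from_state`` of P(s, t) with standard errors and CIs."""
    if t < s:
        raise ValueError(f"horizon t={t} precedes origin s={s}")
    if not 1 <= from_state <= N_STATES:
        raise ValueError(f"state index {from_state} outside 1..{N_STATES}")
    trajectory = aalen_johansen(fit.hazards, s=s, times=np.array([t]))
    return _row_cross_section(trajectory, from_state, t, level, ci_method)


def dynamic_prediction(
    fit: MultiStateFit,
    state_at_s: int,
    s: float,
    horizon: float,
    level: float = 0.95,
) -> pd.DataFrame:
    """Absorbing-outcome probabilities at ``horizon`` for a candidate
    occupying ``state_at_s`` at time ``s``.

    The occupied state must be transient; the Markov assumption makes the
    history before s irrelevant given that state.
    """
    if not 1 <= state_at_s <= N_TRANSIENT:
        raise ValueError("dynamic prediction requires a transient occupied state")
    cs = state_probabilities(fit, state_at_s, s, horizon, level=level)
    rows = []
    for st in fit.space.absorbing:
        k = st.index - 1
        rows.append(
            {
                "outcome": st.label,
                "estimate": cs.probabilities[k],
                "se": cs.standard_errors[k],
                "lower": cs.lower[k],
                "upper": cs.upper[k],
            }
        )
    return pd.DataFrame(rows)


def death_curves(
    fit: MultiStateFit,
    times: np.ndarray,
    level: float = 0.95,
) -> pd.DataFrame:
    """Cumulative death probability from each of the 12 initial states.

    Returns the death/deteriorated column of P(0, t) on the requested grid,
    a step function constant between event times, with CIs.
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    trajectory = aalen_johansen(fit.hazards, s=0.0, times=times)
    lower, upper = confidence_interval(trajectory, level=level)
    death = fit.space.absorbing_index("death_or_deteriorated") - 1
    idx = np.searchsorted(trajectory.times, times, side="right") - 1
    rows = []
    for st in fit.space.transient:
        r = st.index - 1
        for g, t in zip(idx, times):
            rows.append(
                {
                    "initial_state": st.index,
                    "state_label": st.label,
                    "time": t,
                    "estimate": trajectory.probabilities[g, r, death],
                    "se": float(np.sqrt(trajectory.variance[g, r, death])),
                    "lower": lower[g, r, death],
                    "upper": upper[g, r, death],
                }
            )
    return pd.DataFrame(rows)


def compare_cohorts(
    fit_a: MultiStateFit,
    fit_b: MultiStateFit,
    from_state: int,
    target: AbsorbingState | int,
    t: float,
    s: float = 0.0,
    level: float = 0.95,
) -> CohortComparison:
    """Same outcome probability in two independently fitted cohorts.

    Significance is reported descriptively through confidence-interval
    overlap; no formal two-sample test is constructed.
    """
    if fit_a.space.n_states != fit_b.space.n_states or [
        st.label for st in fit_a.space.absorbing
    ] != [st.label for st in fit_b.space.absorbing]:
        raise ValueError("cohort fits live on different state spaces")
    target_index = target.index if isinstance(target, AbsorbingState) else int(target)
    k = target_index - 1
    cs_a = state_probabilities(fit_a, from_state, s, t, level=level)
    cs_b = state_probabilities(fit_b, from_state, s, t, level=level)
    return CohortComparison(
        from_state=from_state,
        target=target_index,
        horizon=t,
        estimate_a=float(cs_a.probabilities[k]),
        estimate_b=float(cs_b.probabilities[k]),
        ci_a=(float(cs_a.lower[k]), float(cs_a.upper[k])),
        ci_b=(float(cs_b.lower[k]), float(cs_b.upper[k])),
        level=level,
    )
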