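r"""Nonparametric estimation for the multi-state Markov model.

Given the stacked long-format transition table, this module computes

* counting-process summaries: at-risk counts :math:`Y_i(u)` per transient
  state and event counts :math:`dN_{ij}(u)` per transition at each observed
  event time,
* Nelson-Aalen cumulative transition hazards
  :math:`\hat A_{ij}(t) = \sum_{u \le t} dN_{ij}(u)/Y_i(u)` with
  Greenwood-type variance increments
  :math:`dN_{ij}(Y_i - dN_{ij})/Y_i^3`,
* Aalen-Johansen transition-probability matrices as the product integral
  :math:`\hat P(s,t) = \prod_{u \in (s,t]} (I + d\hat A(u))`,
* Greenwood-type standard errors for every entry of :math:`\hat P(s,t)` via
  the recursive delta-method propagation of the product factors, and
* normal-approximation confidence bands (linear by default, log-transformed
  optional).

All transitions observed at one event time enter a single product factor, so
each row of every factor sums to one exactly and row-stochasticity of
:math:`\hat P` is preserved to machine precision.  The estimators treat the
process as Markov on time since listing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .state_space import N_STATES, N_TRANSIENT, TransitionStructure

__all__ = [
    "RiskProfile",
    "CumulativeHazardSet",
    "TransitionProbabilityTrajectory",
    "MultiStateFit",
    "count_risk_and_events",
    "nelson_aalen",
    "aalen_johansen",
    "greenwood_variance",
    "confidence_interval",
    "fit_multistate",
]


@dataclass(frozen=True)
class RiskProfile:
    """At-risk and event counts at every observed event time.

    ``at_risk[k, i-1]`` is the number of subject-intervals occupying transient
    state ``i`` just before ``event_times[k]`` (``t_start < u <= t_stop``);
    ``events[k, tid-1]`` counts realized transitions with that id at that time.
    """

    structure: TransitionStructure
    event_times: np.ndarray  # (T,), strictly increasing
    at_risk: np.ndarray  # (T, 12)
    events: np.ndarray  # (T, n_transitions)

    def __post_init__(self) -> None:
        dN_total = np.zeros((len(self.event_times), N_TRANSIENT))
        for f, _t, tid in self.structure.entries:
            dN_total[:, f - 1] += self.events[:, tid - 1]
        if np.any(dN_total > self.at_risk + 1e-9):
            raise ValueError("event count exceeds at-risk count")


def count_risk_and_events(
    table: pd.DataFrame, structure: TransitionStructure
) -> RiskProfile:
    """Tally :math:`Y_i(u)` and :math:`dN_{ij}(u)` from a transition table."""
    events = table.loc[table["status"] == 1]
    event_times = np.unique(events["t_stop"].to_numpy(dtype=float))
    T = len(event_times)
    n_trans = structure.n_transitions

    dN = np.zeros((T, n_trans))
    if T:
        counts = events.groupby(["t_stop", "transition_id"]).size()
        for (u, tid), c in counts.items():
            dN[np.searchsorted(event_times, u), int(tid) - 1] = c

    # one row per interval: dedupe the stacked expansion
    intervals = table.drop_duplicates(["subject_id", "from_index", "t_start", "t_stop"])
    Y = np.zeros((T, N_TRANSIENT))
    for i in range(1, N_TRANSIENT + 1):
        sub = intervals.loc[intervals["from_index"] == i]
        if sub.empty or T == 0:
            continue
        starts = np.sort(sub["t_start"].to_numpy(dtype=float))
        stops = np.sort(sub["t_stop"].to_numpy(dtype=float))
        # at risk just before u: t_start < u and t_stop >= u
        Y[:, i - 1] = np.searchsorted(starts, event_times, side="left") - np.searchsorted(
            stops, event_times, side="left"
        )
    return RiskProfile(
        structure=structure, event_times=event_times, at_risk=Y, events=dN
    )


@dataclass(frozen=True)
class CumulativeHazardSet:
    """Per-transition Nelson-Aalen jump lists with variance increments."""

    structure: TransitionStructure
    event_times: np.ndarray  # (T,)
    delta: np.ndarray  # (T, n_transitions) hazard increments dN/Y
    var_delta: np.ndarray  # (T, n_transitions) variance increments
    at_risk: np.ndarray = field(repr=False, default=None)  # (T, 12)
    events: np.ndarray = field(repr=False, default=None)  # (T, n_transitions)
    variance_method: str = "greenwood"

    def cumulative(self, transition_id: int, times: np.ndarray) -> np.ndarray:
        """A_ij evaluated at ``times`` (right-continuous step function)."""
        jumps = np.cumsum(self.delta[:, transition_id - 1])
        idx = np.searchsorted(self.event_times, times, side="right")
        return np.concatenate([[0.0], jumps])[idx]

    def cumulative_variance(self, transition_id: int, times: np.ndarray) -> np.ndarray:
        jumps = np.cumsum(self.var_delta[:, transition_id - 1])
        idx = np.searchsorted(self.event_times, times, side="right")
        return np.concatenate([[0.0], jumps])[idx]

    def to_frame(self) -> pd.DataFrame:
        """Long format: transition_id, time, dA, var_dA (jumps only)."""
        tids, times, dA, var = [], [], [], []
        for tid in range(1, self.structure.n_transitions + 1):
            mask = self.delta[:, tid - 1] > 0
            tids.extend([tid] * int(mask.sum()))
            times.extend(self.event_times[mask])
            dA.extend(self.delta[mask, tid - 1])
            var.extend(self.var_delta[mask, tid - 1])
        return pd.DataFrame(
            {"transition_id": tids, "time": times, "dA": dA, "var_dA": var}
        )


def nelson_aalen(
    profile: RiskProfile, variance: str = "greenwood"
) -> CumulativeHazardSet:
    """Nelson-Aalen hazard increments dN/Y with a variance increment.

    ``variance`` selects the Greenwood-type increment
    ``dN (Y - dN) / Y^3`` (default; the classical plug-in choice for
    product-limit estimators) or the Poisson-type ``dN / Y^2``.
    """
    if variance not in ("greenwood", "poisson"):
        raise ValueError(f"unknown variance method {variance!r}")
    T = len(profile.event_times)
    n_trans = profile.structure.n_transitions
    delta = np.zeros((T, n_trans))
    var_delta = np.zeros((T, n_trans))
    for f, _t, tid in profile.structure.entries:
        Y = profile.at_risk[:, f - 1]
        dN = profile.events[:, tid - 1]
        with np.errstate(divide="ignore", invalid="ignore"):
            d = np.where(Y > 0, dN / np.maximum(Y, 1), 0.0)
            if variance == "greenwood":
                v = np.where(Y > 0, dN * (Y - dN) / np.maximum(Y, 1) ** 3, 0.0)
            else:
                v = np.where(Y > 0, dN / np.maximum(Y, 1) ** 2, 0.0)
        if np.any((Y <= 0) & (dN > 0)):
            raise RuntimeError("events observed with empty risk set")
        delta[:, tid - 1] = d
        var_delta[:, tid - 1] = v
    return CumulativeHazardSet(
        structure=profile.structure,
        event_times=profile.event_times,
        delta=delta,
        var_delta=var_delta,
        at_risk=profile.at_risk,
        events=profile.events,
        variance_method=variance,
    )


@dataclass(frozen=True)
class TransitionProbabilityTrajectory:
    """Matrix-valued step function P(s, t) on a time grid, with SEs."""

    origin: float
    times: np.ndarray  # (G,), first entry == origin
    probabilities: np.ndarray  # (G, 16, 16)
    variance: np.ndarray | None = None  # (G, 16, 16) entrywise

    def at(self, t: float) -> np.ndarray:
        """P(s, t) for any t >= s (constant between grid times)."""
        idx = int(np.searchsorted(self.times, t, side="right")) - 1
        if idx < 0:
            raise ValueError(f"t={t} precedes origin s={self.origin}")
        return self.probabilities[idx]

    def variance_at(self, t: float) -> np.ndarray:
        if self.variance is None:
            raise ValueError("trajectory carries no variance")
        idx = int(np.searchsorted(self.times, t, side="right")) - 1
        return self.variance[idx]

    @property
    def standard_errors(self) -> np.ndarray:
        return np.sqrt(self.variance)


def _factor(delta_row: np.ndarray, structure: TransitionStructure) -> np.ndarray:
    """I + dA(u) from one row of hazard increments."""
    B = np.eye(N_STATES)
    for f, t, tid in structure.entries:
        d = delta_row[tid - 1]
        if d:
            B[f - 1, t - 1] += d
            B[f - 1, f - 1] -= d
    return B


def _row_covariances(
    hazards: CumulativeHazardSet, k: int
) -> np.ndarray:
    """cov(dA_i. , dA_i.) at event time index k, per transient row i.

    Within a row the event counts are multinomial over destinations; the
    Greenwood-type estimator is
    ``cov(dA_ij, dA_il) = (delta_jl Y_i dN_ij - dN_ij dN_il) / Y_i^3``;
    the diagonal generator entry ``dA_ii = -sum_j dA_ij`` enters by linearity.
    Poisson-type variance drops the multinomial correction.
    """
    R = np.zeros((N_STATES, N_STATES, N_STATES))
    dN_row = np.zeros((N_TRANSIENT, N_STATES))
    for f, t, tid in hazards.structure.entries:
        dN_row[f - 1, t - 1] = hazards.events[k, tid - 1]
    for i in range(N_TRANSIENT):
        Y = hazards.at_risk[k, i]
        dN = dN_row[i]
        if Y <= 0 or not dN.any():
            continue
        if hazards.variance_method == "poisson":
            C = np.diag(dN) / Y**2
        else:
            C = (np.diag(Y * dN) - np.outer(dN, dN)) / Y**3
        # fold in the diagonal entry -sum_j dA_ij
        C[i, :] = -C.sum(axis=0)
        C[:, i] = -C.sum(axis=1)
        R[i] = C
    return R


def aalen_johansen(
    hazards: CumulativeHazardSet,
    s: float = 0.0,
    times: np.ndarray | None = None,
    with_variance: bool = True,
) -> TransitionProbabilityTrajectory:
    """Aalen-Johansen product-integral estimate of P(s, t).

    The grid is the union of observed event times in (s, t_max] and any
    requested ``times``; absorbing rows stay unit vectors and P(s, s) = I.
    When ``with_variance`` the recursive Greenwood-type covariance is
    propagated and entrywise variances are stored alongside.
    """
    if s < 0:
        raise ValueError("origin s must be non-negative")
    structure = hazards.structure
    req = np.asarray([] if times is None else np.atleast_1d(times), dtype=float)
    req = req[req >= s]  # times before the origin carry no information
    ev = hazards.event_times
    ev_after = ev[ev > s]
    t_max = max([s, *req.tolist(), *ev_after.tolist()])
    grid = np.unique(np.concatenate([[s], ev_after[ev_after <= t_max], req]))
    if len(ev) and s > ev[-1]:
        import warnings

        warnings.warn("origin s lies beyond the last observed event time")

    P = np.eye(N_STATES)
    V = np.zeros((N_STATES, N_STATES, N_STATES, N_STATES)) if with_variance else None
    probs = np.empty((len(grid), N_STATES, N_STATES))
    var = np.empty_like(probs) if with_variance else None

    ev_idx = {u: k for k, u in enumerate(ev)}
    for g, t in enumerate(grid):
        if t > s and t in ev_idx:
            k = ev_idx[t]
            B = _factor(hazards.delta[k], structure)
            if with_variance:
                R = _row_covariances(hazards, k)
                # vec P(u) = vec(P(u-) B); delta-method update
                V = np.einsum("axcy,xb,yd->abcd", V, B, B, optimize=True)
                V += np.einsum("ai,ci,ibd->abcd", P, P, R, optimize=True)
            P = P @ B
        probs[g] = P
        if with_variance:
            var[g] = np.einsum("abab->ab", V)
    return TransitionProbabilityTrajectory(
        origin=s, times=grid, probabilities=probs, variance=var
    )


def greenwood_variance(
    hazards: CumulativeHazardSet,
    trajectory: TransitionProbabilityTrajectory,
) -> np.ndarray:
    """Entrywise standard errors of P(s, t) on the trajectory's grid.

    Recomputes the recursive covariance propagation from the hazard set; the
    result matches the classical Greenwood formula on two-state reductions.
    """
    recomputed = aalen_johansen(
        hazards,
        s=trajectory.origin,
        times=trajectory.times,
        with_variance=True,
    )
    idx = np.searchsorted(recomputed.times, trajectory.times, side="right") - 1
    return np.sqrt(recomputed.variance[idx])


def confidence_interval(
    trajectory: TransitionProbabilityTrajectory,
    level: float = 0.95,
    method: str = "linear",
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise normal-approximation bands for every entry of P(s, t).

    ``linear`` bands are ``p +/- z se`` truncated to [0, 1]; ``log`` bands
    apply the normal approximation on the log scale, ``p exp(+/- z se / p)``,
    which keeps the lower bound positive for positive estimates (entries at
    exactly 0 keep degenerate bounds).
    """
    if not 0 < level < 1:
        raise ValueError("confidence level must lie in (0, 1)")
    if trajectory.variance is None:
        raise ValueError("trajectory carries no variance")
    z = stats.norm.ppf(0.5 + level / 2)
    p = trajectory.probabilities
    se = np.sqrt(trajectory.variance)
    if method == "linear":
        lower = np.clip(p - z * se, 0.0, 1.0)
        upper = np.clip(p + z * se, 0.0, 1.0)
    elif method == "log":
        with np.errstate(divide="ignore", invalid="ignore"):
            factor = np.exp(np.where(p > 0, z * se / np.maximum(p, 1e-300), 0.0))
        lower = np.clip(np.where(p > 0, p / factor, 0.0), 0.0, 1.0)
        upper = np.clip(np.where(p > 0, p * factor, 0.0), 0.0, 1.0)
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return lower, upper


@dataclass(frozen=True)
class MultiStateFit:
    """A fitted multi-state model: counting processes plus hazard set."""

    structure: TransitionStructure
    table: pd.DataFrame = field(repr=False)
    profile: RiskProfile = field(repr=False)
    hazards: CumulativeHazardSet = field(repr=False)

    @property
    def space(self):
        return self.structure.space

    def transition_probabilities(
        self, s: float = 0.0, times=None, with_variance: bool = True
    ) -> TransitionProbabilityTrajectory:
        return aalen_johansen(self.hazards, s=s, times=times, with_variance=with_variance)

    @property
    def n_subjects(self) -> int:
        return self.table["subject_id"].nunique()


def fit_multistate(
    table: pd.DataFrame,
    structure: TransitionStructure,
    variance: str = "greenwood",
) -> MultiStateFit:
    """Run the counting-process tally and Nelson-Aalen step on a table."""
    profile = count_risk_and_events(table, structure)
    hazards = nelson_aalen(profile, variance=variance)
    return MultiStateFit(
        structure=structure, table=table, profile=profile, hazards=hazards
    )
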