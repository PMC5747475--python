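"""Seeded simulation of waitlist cohorts on the 16-state space.

Registry extracts of real waitlist trajectories are access-restricted, so
model building and validation run against synthetic cohorts drawn from a
time-inhomogeneous Markov process with piecewise-constant transition
intensities over the allowed-transition structure.  The same intensity model
yields an exact analytic transition-probability oracle (products of matrix
exponentials), which is what the nonparametric estimators are validated
against.

Sampling is exact: holding times come from inversion of the piecewise-
constant total exit intensity, destinations from the intensity ratios at the
jump instant.  Each subject consumes the single seeded stream in a
documented order (initial state, listing-date offset, covariates, censoring
draw, then alternating holding-time/destination draws), so a fixed seed and
configuration reproduce the cohort exactly.

Continuous-time paths are encoded into :class:`RegistrantRecord` on an
integer-day grid (the registry's effective resolution): jump times round up
to whole days and are bumped forward where two jumps would collide on one
day, so the encoded record realizes exactly the simulated jump sequence.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

from .event_history import RegistrantRecord, Update
from .state_space import (
    ActivityStatus,
    N_STATES,
    N_TRANSIENT,
    StateSpace,
    TransitionStructure,
    build_state_space,
    build_transition_structure,
)

__all__ = [
    "IntensityModel",
    "ScenarioConfig",
    "SimulatedPath",
    "simulate_subject",
    "simulate_cohort",
    "simulate_paths",
    "true_transition_probability",
    "default_scenario",
    "validation_scenario",
]

#: representative integer CPRA percent written into records for each category
CATEGORY_REPRESENTATIVE_CPRA = {1: 0, 2: 40, 3: 85, 4: 92, 5: 96, 6: 99}


@dataclass(frozen=True)
class IntensityModel:
    """Piecewise-constant intensities over the allowed transitions.

    ``breakpoints`` start at day 0; piece ``p`` covers
    ``[breakpoints[p], breakpoints[p+1])`` (the last piece extends to
    infinity).  ``rates[p, tid-1]`` is the per-day intensity of transition
    ``tid`` within piece ``p``.  Forbidden transitions have no rate slot at
    all, so an inactive state can never jump straight to deceased-donor
    transplant.
    """

    structure: TransitionStructure
    breakpoints: np.ndarray  # (P,), increasing, starts at 0
    rates: np.ndarray  # (P, n_transitions), non-negative

    def __post_init__(self) -> None:
        bp = np.asarray(self.breakpoints, dtype=float)
        rt = np.atleast_2d(np.asarray(self.rates, dtype=float))
        object.__setattr__(self, "breakpoints", bp)
        object.__setattr__(self, "rates", rt)
        if bp[0] != 0 or np.any(np.diff(bp) <= 0):
            raise ValueError("breakpoints must start at 0 and increase")
        if rt.shape != (len(bp), self.structure.n_transitions):
            raise ValueError("rates must be (n_pieces, n_transitions)")
        if np.any(rt < 0) or not np.all(np.isfinite(rt)):
            raise ValueError("rates must be finite and non-negative")

    @classmethod
    def homogeneous(
        cls, structure: TransitionStructure, rate_by_pair: dict[tuple[int, int], float]
    ) -> "IntensityModel":
        """Single-piece model from a {(from, to): rate-per-day} mapping."""
        rates = np.zeros((1, structure.n_transitions))
        for (f, t), r in rate_by_pair.items():
            rates[0, structure.transition_id(f, t) - 1] = r
        return cls(structure=structure, breakpoints=np.array([0.0]), rates=rates)

    @property
    def n_pieces(self) -> int:
        return len(self.breakpoints)

    def piece_at(self, t: float) -> int:
        return int(np.searchsorted(self.breakpoints, t, side="right")) - 1

    def generator(self, piece: int) -> np.ndarray:
        """16x16 generator Q for one piece (absorbing rows zero)."""
        Q = np.zeros((N_STATES, N_STATES))
        for f, t, tid in self.structure.entries:
            Q[f - 1, t - 1] = self.rates[piece, tid - 1]
        np.fill_diagonal(Q, Q.diagonal() - Q.sum(axis=1))
        return Q

    def exit_rate(self, state: int, piece: int) -> float:
        total = 0.0
        for f, _t, tid in self.structure.entries:
            if f == state:
                total += self.rates[piece, tid - 1]
        return total


def true_transition_probability(
    model: IntensityModel, s: float, t: float
) -> np.ndarray:
    """Exact P(s, t) = product over pieces of exp(duration * Q_piece)."""
    if t < s:
        raise ValueError("t must be >= s")
    P = np.eye(N_STATES)
    if t == s:
        return P
    bounds = list(model.breakpoints) + [np.inf]
    for p in range(model.n_pieces):
        lo, hi = max(bounds[p], s), min(bounds[p + 1], t)
        if hi > lo:
            P = P @ expm(model.generator(p) * (hi - lo))
    return P


@dataclass(frozen=True)
class ScenarioConfig:
    """One reproducible simulated-cohort scenario.

    ``initial_state_distribution`` is over the 12 transient states in index
    order.  ``censoring_rate`` draws an independent exponential dropout time
    per subject (None disables it); every subject is administratively
    censored at ``admin_horizon_day``.  Listing dates spread uniformly over
    ``listing_spread_days`` days from ``listing_date_start`` so that
    calendar-anchored censoring schemes can be exercised.
    """

    intensities: IntensityModel
    n_subjects: int = 1000
    seed: int = 0
    initial_state_distribution: np.ndarray = field(
        default_factory=lambda: np.full(N_TRANSIENT, 1.0 / N_TRANSIENT)
    )
    censoring_rate: float | None = None
    admin_horizon_day: int = 1095
    listing_date_start: dt.date = dt.date(2009, 10, 1)
    listing_spread_days: int = 0

    def __post_init__(self) -> None:
        dist = np.asarray(self.initial_state_distribution, dtype=float)
        object.__setattr__(self, "initial_state_distribution", dist)
        if dist.shape != (N_TRANSIENT,) or abs(dist.sum() - 1) > 1e-8 or dist.min() < 0:
            raise ValueError("initial distribution must be a 12-probability vector")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.admin_horizon_day is None and self.censoring_rate is None:
            for p in range(self.intensities.n_pieces):
                for i in range(1, N_TRANSIENT + 1):
                    if self.intensities.exit_rate(i, p) == 0:
                        raise ValueError(
                            "zero exit rates with no horizon would never terminate"
                        )


@dataclass(frozen=True)
class SimulatedPath:
    """Exact continuous-time trajectory of one subject."""

    subject_id: str
    initial_state: int
    jump_times: tuple[float, ...]  # strictly increasing
    jump_states: tuple[int, ...]  # state entered at each jump
    end_time: float  # absorption or censoring time
    absorbed: bool  # True iff the last jump_state is absorbing

    @property
    def transitions(self) -> list[tuple[int, int]]:
        states = (self.initial_state,) + self.jump_states
        return list(zip(states, states[1:]))


def _sample_holding_time(
    model: IntensityModel, state: int, start: float, rng: np.random.Generator
) -> float:
    """Inversion sampling of the next jump time from ``start`` in ``state``.

    Integrates the piecewise-constant exit intensity until it exhausts a unit
    exponential draw; returns ``inf`` if the hazard never accumulates enough.
    """
    target = rng.exponential(1.0)
    bounds = list(model.breakpoints) + [np.inf]
    t = start
    for p in range(model.piece_at(start), model.n_pieces):
        lam = model.exit_rate(state, p)
        width = bounds[p + 1] - t
        if lam > 0:
            if lam * width >= target:
                return t + target / lam
            target -= lam * width
        t = bounds[p + 1]
    return np.inf


def _sample_destination(
    model: IntensityModel, state: int, t: float, rng: np.random.Generator
) -> int:
    piece = model.piece_at(t)
    dests, weights = [], []
    for f, to, tid in model.structure.entries:
        if f == state:
            r = model.rates[piece, tid - 1]
            if r > 0:
                dests.append(to)
                weights.append(r)
    w = np.asarray(weights)
    return dests[rng.choice(len(dests), p=w / w.sum())]


def _sample_covariates(rng: np.random.Generator) -> tuple[float, dict[str, str]]:
    """Plausible demographic covariates for a synthetic registrant."""
    age = float(rng.uniform(19, 80))
    age_group = "18-39" if age < 40 else ("40-64" if age < 65 else ">=65")
    gender = str(rng.choice(["Male", "Female"], p=[0.61, 0.39]))
    abo = str(rng.choice(["O", "A", "B", "AB"], p=[0.48, 0.34, 0.14, 0.04]))
    race = str(
        rng.choice(
            ["White", "Black", "Hispanic", "Asian", "Other"],
            p=[0.44, 0.29, 0.18, 0.07, 0.02],
        )
    )
    esrd = str(
        rng.choice(
            ["Diabetes", "Glomerulonephritis", "Graft Failure", "Hypertension", "Other"],
            p=[0.36, 0.11, 0.02, 0.23, 0.28],
        )
    )
    return age, {
        "age_group": age_group,
        "gender": gender,
        "abo": abo,
        "race": race,
        "esrd_diagnosis": esrd,
    }


def _simulate_one(
    config: ScenarioConfig, subject_id: str, rng: np.random.Generator
) -> tuple[SimulatedPath, RegistrantRecord]:
    space = config.intensities.structure.space
    state = int(
        rng.choice(np.arange(1, N_TRANSIENT + 1), p=config.initial_state_distribution)
    )
    offset = int(rng.integers(0, config.listing_spread_days + 1))
    listing_date = config.listing_date_start + dt.timedelta(days=offset)
    age, covariates = _sample_covariates(rng)
    censor_time = (
        rng.exponential(1.0 / config.censoring_rate)
        if config.censoring_rate
        else np.inf
    )
    horizon = (
        float(config.admin_horizon_day)
        if config.admin_horizon_day is not None
        else np.inf
    )
    end_obs = min(censor_time, horizon)

    jump_times: list[float] = []
    jump_states: list[int] = []
    t, cur = 0.0, state
    absorbed = False
    while True:
        nxt = _sample_holding_time(config.intensities, cur, t, rng)
        if nxt >= end_obs:
            break
        dest = _sample_destination(config.intensities, cur, nxt, rng)
        jump_times.append(nxt)
        jump_states.append(dest)
        t, cur = nxt, dest
        if space.is_absorbing(dest):
            absorbed = True
            break
    end_time = jump_times[-1] if absorbed else end_obs
    path = SimulatedPath(
        subject_id=subject_id,
        initial_state=state,
        jump_times=tuple(jump_times),
        jump_states=tuple(jump_states),
        end_time=end_time,
        absorbed=absorbed,
    )
    record = _encode_record(path, space, listing_date, age, covariates, end_obs)
    return path, record


def _state_to_cpra_status(space: StateSpace, index: int) -> tuple[int, ActivityStatus]:
    st = space.transient[index - 1]
    return CATEGORY_REPRESENTATIVE_CPRA[st.cpra.index], st.status


def _encode_record(
    path: SimulatedPath,
    space: StateSpace,
    listing_date: dt.date,
    age: float,
    covariates: dict[str, str],
    end_obs: float,
) -> RegistrantRecord:
    """Round a continuous path onto the integer-day registry grid.

    Jump times round up to whole days; colliding days are pushed forward one
    day each so the day sequence is strictly increasing and the record
    re-derives to exactly the simulated jump sequence.
    """
    cpra0, status0 = _state_to_cpra_status(space, path.initial_state)
    days: list[int] = []
    for t in path.jump_times:
        d = max(int(np.ceil(t)), 1)
        if days and d <= days[-1]:
            d = days[-1] + 1
        days.append(d)

    updates: list[Update] = []
    terminal_day: int | None = None
    terminal_state: int | None = None
    for d, st in zip(days, path.jump_states):
        if space.is_absorbing(st):
            terminal_day, terminal_state = d, st
        else:
            cpra, status = _state_to_cpra_status(space, st)
            updates.append(Update(day=d, cpra=cpra, status=status))

    censor_day: int | None = None
    if terminal_day is None:
        censor_day = int(np.ceil(end_obs)) if np.isfinite(end_obs) else None
        if censor_day is not None and days:
            censor_day = max(censor_day, days[-1] + 1)
    return RegistrantRecord(
        subject_id=path.subject_id,
        listing_date=listing_date,
        age_at_listing=age,
        initial_cpra=cpra0,
        initial_status=status0,
        first_time=True,
        multi_organ=False,
        covariates=covariates,
        updates=updates,
        terminal_day=terminal_day,
        terminal_state=terminal_state,
        censor_day=censor_day,
    )


def _run(config: ScenarioConfig) -> list[tuple[SimulatedPath, RegistrantRecord]]:
    rng = np.random.default_rng(config.seed)
    width = len(str(config.n_subjects))
    return [
        _simulate_one(config, f"S{k + 1:0{width}d}", rng)
        for k in range(config.n_subjects)
    ]


def simulate_subject(
    config: ScenarioConfig, rng: np.random.Generator, subject_id: str = "S1"
) -> RegistrantRecord:
    """Draw one registrant record from an externally managed stream."""
    return _simulate_one(config, subject_id, rng)[1]


def simulate_cohort(config: ScenarioConfig) -> list[RegistrantRecord]:
    """Simulate the full cohort; identical seed + config reproduce it exactly."""
    return [rec for _path, rec in _run(config)]


def simulate_paths(config: ScenarioConfig) -> list[SimulatedPath]:
    """Continuous-time view of the same cohort ``simulate_cohort`` encodes."""
    return [path for path, _rec in _run(config)]


def _default_rate_map(
    structure: TransitionStructure,
    *,
    deceased_donor_by_category: dict[int, float],
    living_donor: float,
    death_active: float,
    death_inactive: float,
    removed_other: float,
    inactivation: float,
    reactivation: float,
    cpra_adjacent: float,
    cpra_distant: float,
) -> dict[tuple[int, int], float]:
    """Assemble a per-day rate map from interpretable components.

    CPRA moves preserve activity status; activation moves preserve category.
    Simultaneous category-and-status jumps get rate zero (they remain allowed
    transitions with no intensity).
    """
    space = structure.space
    dd = space.absorbing_index("deceased_donor_transplant")
    ld = space.absorbing_index("living_donor_transplant")
    dth = space.absorbing_index("death_or_deteriorated")
    rem = space.absorbing_index("removed_other")
    rates: dict[tuple[int, int], float] = {}
    for st in space.transient:
        i = st.index
        active = st.status is ActivityStatus.ACTIVE
        if active:
            rates[(i, dd)] = deceased_donor_by_category[st.cpra.index]
        rates[(i, ld)] = living_donor
        rates[(i, dth)] = death_active if active else death_inactive
        rates[(i, rem)] = removed_other
        # status flip within category
        partner = StateSpace.index_of(
            st.cpra.index,
            ActivityStatus.INACTIVE if active else ActivityStatus.ACTIVE,
        )
        rates[(i, partner)] = inactivation if active else reactivation
        # CPRA moves within status
        for other in space.transient:
            if other.status is st.status and other.cpra.index != st.cpra.index:
                gap = abs(other.cpra.index - st.cpra.index)
                rates[(i, other.index)] = cpra_adjacent if gap == 1 else cpra_distant
    return rates


def default_scenario(
    n_subjects: int = 1000, seed: int = 0, **overrides
) -> ScenarioConfig:
    """Cohort emulating a waitlist registry's shape.

    The initial distribution concentrates ~98% of registrants in the two
    lowest CPRA categories (as registry demographics do), mostly listed
    active; deceased-donor intensities fall with CPRA (a pre-policy-change
    pattern), death intensity is elevated from inactive states, and CPRA
    moves are mostly between adjacent categories.  Rates are per day and are
    illustrative of registry magnitudes, not estimates of them.
    """
    space = build_state_space()
    structure = build_transition_structure(space)
    rates = _default_rate_map(
        structure,
        deceased_donor_by_category={1: 4e-4, 2: 4e-4, 3: 3.5e-4, 4: 3e-4, 5: 2e-4, 6: 1e-4},
        living_donor=1.5e-4,
        death_active=1.2e-4,
        death_inactive=3.5e-4,
        removed_other=6e-5,
        inactivation=8e-4,
        reactivation=1.6e-3,
        cpra_adjacent=2e-4,
        cpra_distant=2e-5,
    )
    model = IntensityModel.homogeneous(structure, rates)
    cat_probs = {1: 0.555, 2: 0.426, 3: 0.0059, 4: 0.0036, 5: 0.0045, 6: 0.0051}
    dist = np.zeros(N_TRANSIENT)
    for c, pc in cat_probs.items():
        dist[StateSpace.index_of(c, ActivityStatus.ACTIVE) - 1] = pc * 0.85
        dist[StateSpace.index_of(c, ActivityStatus.INACTIVE) - 1] = pc * 0.15
    dist /= dist.sum()
    kwargs = dict(
        intensities=model,
        n_subjects=n_subjects,
        seed=seed,
        initial_state_distribution=dist,
        censoring_rate=2e-4,
        admin_horizon_day=1095,
    )
    kwargs.update(overrides)
    return ScenarioConfig(**kwargs)


def validation_scenario(
    n_subjects: int = 1000, seed: int = 0, **overrides
) -> ScenarioConfig:
    """Estimator-validation cohort: uniform start over all 12 states.

    Used to check estimator recovery against the analytic oracle: every row
    of P(0, t) must be informed, so initial mass is spread uniformly and
    rates are at the high end of realistic registry magnitudes to yield
    informative event counts at moderate n.
    """
    space = build_state_space()
    structure = build_transition_structure(space)
    rates = _default_rate_map(
        structure,
        deceased_donor_by_category={1: 1e-3, 2: 1e-3, 3: 9e-4, 4: 8e-4, 5: 7e-4, 6: 6e-4},
        living_donor=3e-4,
        death_active=5e-4,
        death_inactive=1e-3,
        removed_other=2e-4,
        inactivation=1.2e-3,
        reactivation=2.5e-3,
        cpra_adjacent=3e-4,
        cpra_distant=3e-5,
    )
    model = IntensityModel.homogeneous(structure, rates)
    kwargs = dict(
        intensities=model,
        n_subjects=n_subjects,
        seed=seed,
        initial_state_distribution=np.full(N_TRANSIENT, 1.0 / N_TRANSIENT),
        censoring_rate=None,
        admin_horizon_day=730,
    )
    kwargs.update(overrides)
    return ScenarioConfig(**kwargs)
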