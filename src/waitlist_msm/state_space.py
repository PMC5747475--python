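"""State space of the kidney-waitlist multi-state model.

Registrants occupy one of 12 transient states — the product of six CPRA
(Calculated Panel Reactive Antibodies) categories and two waitlist activity
statuses — until they reach one of four absorbing outcomes: deceased-donor
transplant, living-donor transplant, death or removal for deteriorating
condition, or removal for other reasons.

The CPRA categories follow US allocation-policy breakpoints: 0%, 1-79%,
80-89%, 90-94%, 95-98%, 99-100%.  Candidates with CPRA >= 80% historically
received priority points, candidates at 99/100% receive regional/national
priority, hence the fine partition at the top of the scale.

Allowed transitions connect every transient state to every other transient
state and to every absorbing state, except that an inactive candidate cannot
receive a deceased-donor transplant directly (inactive candidates do not
receive deceased-donor offers).  That yields 12*15 - 6 = 174 transitions.

State indices are fixed: transient states 1-12 are ordered by (CPRA category,
active-before-inactive); absorbing states are 13 = deceased-donor transplant,
14 = living-donor transplant, 15 = death/deteriorated, 16 = removed-other.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Sequence

__all__ = [
    "ActivityStatus",
    "CpraCategory",
    "TransientState",
    "AbsorbingState",
    "StateSpace",
    "TransitionStructure",
    "DEFAULT_CPRA_BOUNDS",
    "ABSORBING_LABELS",
    "N_STATES",
    "N_TRANSIENT",
    "N_ABSORBING",
    "categorize_cpra",
    "build_state_space",
    "build_transition_structure",
]

#: (lower, upper) integer CPRA percent bounds, inclusive on both ends.
DEFAULT_CPRA_BOUNDS: tuple[tuple[int, int], ...] = (
    (0, 0),
    (1, 79),
    (80, 89),
    (90, 94),
    (95, 98),
    (99, 100),
)

ABSORBING_LABELS: tuple[str, ...] = (
    "deceased_donor_transplant",
    "living_donor_transplant",
    "death_or_deteriorated",
    "removed_other",
)

N_TRANSIENT = 12
N_ABSORBING = 4
N_STATES = N_TRANSIENT + N_ABSORBING

#: index (1-based) of the deceased-donor absorbing state
DECEASED_DONOR_INDEX = N_TRANSIENT + 1


class ActivityStatus(str, enum.Enum):
    """Eligibility to receive deceased-donor offers."""

    ACTIVE = "active"
    INACTIVE = "inactive"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class CpraCategory:
    """One CPRA percent band, inclusive integer bounds."""

    index: int
    lower: int
    upper: int

    @property
    def label(self) -> str:
        if self.lower == self.upper:
            return f"{self.lower}%"
        return f"{self.lower}-{self.upper}%"

    def contains(self, cpra_int: int) -> bool:
        return self.lower <= cpra_int <= self.upper


@dataclass(frozen=True)
class TransientState:
    index: int
    cpra: CpraCategory
    status: ActivityStatus

    @property
    def label(self) -> str:
        return f"{self.cpra.label} {self.status.value}"


@dataclass(frozen=True)
class AbsorbingState:
    index: int
    label: str


def _make_categories(
    bounds: Sequence[tuple[int, int]] = DEFAULT_CPRA_BOUNDS,
) -> tuple[CpraCategory, ...]:
    cats = tuple(
        CpraCategory(index=i + 1, lower=lo, upper=hi)
        for i, (lo, hi) in enumerate(bounds)
    )
    covered = sorted(v for c in cats for v in range(c.lower, c.upper + 1))
    if covered != list(range(bounds[0][0], bounds[-1][1] + 1)):
        raise ValueError("CPRA category bounds must partition the percent range")
    return cats


def categorize_cpra(
    cpra: float, bounds: Sequence[tuple[int, int]] = DEFAULT_CPRA_BOUNDS
) -> CpraCategory:
    """Map a CPRA percent to its category.

    Fractional values are floored first: CPRA is reported as an integer
    percent in registry practice, so e.g. 89.4 belongs to the 80-89% band and
    any value strictly between 0 and 1 belongs to the 0% band.

    Raises
    ------
    ValueError
        If ``cpra`` lies outside [0, 100].
    """
    if not (0 <= cpra <= 100):
        raise ValueError(f"CPRA must lie in [0, 100], got {cpra!r}")
    value = math.floor(cpra)
    for cat in _make_categories(bounds):
        if cat.contains(value):
            return cat
    raise ValueError(f"no CPRA category contains {cpra!r}")  # pragma: no cover


@dataclass(frozen=True)
class StateSpace:
    """The canonical 16-state space (12 transient + 4 absorbing)."""

    transient: tuple[TransientState, ...]
    absorbing: tuple[AbsorbingState, ...]
    categories: tuple[CpraCategory, ...] = field(repr=False, default=())

    @property
    def n_states(self) -> int:
        return len(self.transient) + len(self.absorbing)

    @property
    def n_transient(self) -> int:
        return len(self.transient)

    def state_label(self, index: int) -> str:
        if 1 <= index <= len(self.transient):
            return self.transient[index - 1].label
        return self.absorbing[index - 1 - len(self.transient)].label

    def transient_index(self, cpra: float, status: ActivityStatus) -> int:
        """1-based state index occupied by a candidate with this CPRA/status."""
        cat = categorize_cpra(cpra, [(c.lower, c.upper) for c in self.categories])
        return self.index_of(cat.index, status)

    @staticmethod
    def index_of(category_index: int, status: ActivityStatus) -> int:
        """Index from (category, status); active precedes inactive."""
        return 2 * (category_index - 1) + (1 if status is ActivityStatus.ACTIVE else 2)

    def absorbing_index(self, label: str) -> int:
        for st in self.absorbing:
            if st.label == label:
                return st.index
        raise KeyError(label)

    def is_absorbing(self, index: int) -> bool:
        return index > len(self.transient)


def build_state_space(
    bounds: Sequence[tuple[int, int]] = DEFAULT_CPRA_BOUNDS,
) -> StateSpace:
    """Construct the canonical state space.

    Transient indices run over CPRA categories in increasing order, active
    before inactive within a category; the four absorbing outcomes follow.
    """
    cats = _make_categories(bounds)
    transient = []
    for cat in cats:
        for status in (ActivityStatus.ACTIVE, ActivityStatus.INACTIVE):
            transient.append(
                TransientState(
                    index=StateSpace.index_of(cat.index, status),
                    cpra=cat,
                    status=status,
                )
            )
    absorbing = tuple(
        AbsorbingState(index=len(transient) + 1 + k, label=lab)
        for k, lab in enumerate(ABSORBING_LABELS)
    )
    return StateSpace(transient=tuple(transient), absorbing=absorbing, categories=cats)


@dataclass(frozen=True)
class TransitionStructure:
    """Enumeration of allowed transitions with contiguous 1-based ids.

    ``entries`` is ordered by (from_index, to_index); ids are 1..n_transitions.
    """

    space: StateSpace
    entries: tuple[tuple[int, int, int], ...]  # (from_index, to_index, id)

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "_id_by_pair",
            {(f, t): i for f, t, i in self.entries},
        )
        object.__setattr__(self, "_pair_by_id", {i: (f, t) for f, t, i in self.entries})

    @property
    def n_transitions(self) -> int:
        return len(self.entries)

    def transition_id(self, from_index: int, to_index: int) -> int:
        try:
            return self._id_by_pair[(from_index, to_index)]
        except KeyError:
            raise KeyError(
                f"transition {from_index}->{to_index} is not allowed"
            ) from None

    def pair(self, transition_id: int) -> tuple[int, int]:
        return self._pair_by_id[transition_id]

    def is_allowed(self, from_index: int, to_index: int) -> bool:
        return (from_index, to_index) in self._id_by_pair

    def destinations(self, from_index: int) -> list[int]:
        return [t for f, t, _ in self.entries if f == from_index]


def build_transition_structure(space: StateSpace) -> TransitionStructure:
    """Enumerate allowed transitions.

    Every transient state connects to every other transient state and every
    absorbing state, except inactive -> deceased-donor transplant (inactive
    candidates are ineligible for deceased-donor offers).  No self-loops.
    """
    dd = space.absorbing_index("deceased_donor_transplant")
    entries: list[tuple[int, int, int]] = []
    next_id = 1
    for st in space.transient:
        for to_index in range(1, space.n_states + 1):
            if to_index == st.index:
                continue
            if st.status is ActivityStatus.INACTIVE and to_index == dd:
                continue
            entries.append((st.index, to_index, next_id))
            next_id += 1
    return TransitionStructure(space=space, entries=tuple(entries))
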