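"""Cohort characterization: category counts, percentages, balance.

Demographic tables compare two cohorts (e.g. registrants listed before vs
after an allocation-policy change) variable by variable.  Balance between
cohorts is measured with standardized differences: the two-proportion
Cohen's-d-type formula for binary variables and the Mahalanobis-type
multivariate standardized difference for variables with more than two
categories.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .event_history import COVARIATE_KEYS, RegistrantRecord

__all__ = [
    "CategoricalSummary",
    "summarize",
    "summary_from_counts",
    "standardized_difference",
    "compare_cohorts_table",
]

#: canonical category orders for the registry variables
CATEGORY_ORDERS = {
    "age_group": ["18-39", "40-64", ">=65"],
    "gender": ["Male", "Female"],
    "abo": ["O", "A", "B", "AB"],
    "race": ["White", "Black", "Hispanic", "Asian", "Other"],
    "esrd_diagnosis": [
        "Diabetes",
        "Glomerulonephritis",
        "Graft Failure",
        "Hypertension",
        "Other",
    ],
}


@dataclass(frozen=True)
class CategoricalSummary:
    """Counts and percentages of one variable in one cohort."""

    variable: str
    categories: tuple[str, ...]
    counts: tuple[int, ...]
    total: int

    @property
    def percents(self) -> np.ndarray:
        """Exact percentages (100 * count / total); 0 with an empty cohort."""
        if self.total == 0:
            return np.zeros(len(self.counts))
        return 100.0 * np.asarray(self.counts, dtype=float) / self.total

    @property
    def proportions(self) -> np.ndarray:
        if self.total == 0:
            return np.zeros(len(self.counts))
        return np.asarray(self.counts, dtype=float) / self.total


def summarize(records: Iterable[RegistrantRecord], variable: str) -> CategoricalSummary:
    """Exact category counts of one covariate over a cohort."""
    if variable not in COVARIATE_KEYS:
        raise ValueError(
            f"unknown variable {variable!r}; expected one of {COVARIATE_KEYS}"
        )
    values = [rec.covariates.get(variable, "") for rec in records]
    order = CATEGORY_ORDERS.get(variable)
    if order is None:
        order = sorted(set(values))
    extra = sorted(set(values) - set(order) - {""})
    cats = tuple(order) + tuple(extra)
    counts = tuple(values.count(c) for c in cats)
    return CategoricalSummary(
        variable=variable, categories=cats, counts=counts, total=len(values)
    )


def summary_from_counts(
    variable: str, categories: Sequence[str], counts: Sequence[int]
) -> CategoricalSummary:
    """Build a summary from published per-category counts."""
    counts = tuple(int(c) for c in counts)
    if any(c < 0 for c in counts):
        raise ValueError("counts must be non-negative")
    return CategoricalSummary(
        variable=variable,
        categories=tuple(categories),
        counts=counts,
        total=sum(counts),
    )


def standardized_difference(p1: Sequence[float], p2: Sequence[float]) -> float:
    """Standardized difference between two categorical distributions.

    For binary variables this is the two-proportion formula
    ``|p1 - p2| / sqrt((p1 (1-p1) + p2 (1-p2)) / 2)``.  For k > 2 categories
    it is the Mahalanobis-type multivariate standardized difference over the
    first k-1 categories with the averaged multinomial covariance
    ``S = (S1 + S2) / 2``, ``S_c[j, l] = p_c[j] (delta_jl - p_c[l])``.
    Symmetric in its arguments and zero iff they are equal.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if p1.shape != p2.shape or p1.ndim != 1 or len(p1) < 2:
        raise ValueError("need two equal-length proportion vectors of length >= 2")
    for p in (p1, p2):
        if abs(p.sum() - 1.0) > 1e-8 or p.min() < 0:
            raise ValueError("proportion vectors must be non-negative and sum to 1")
    if np.allclose(p1, p2, atol=0, rtol=0):
        return 0.0
    if len(p1) == 2:
        a, b = p1[0], p2[0]
        denom = np.sqrt((a * (1 - a) + b * (1 - b)) / 2.0)
        if denom == 0:
            return np.inf
        return float(abs(a - b) / denom)
    d = (p1 - p2)[:-1]
    S1 = np.diag(p1[:-1]) - np.outer(p1[:-1], p1[:-1])
    S2 = np.diag(p2[:-1]) - np.outer(p2[:-1], p2[:-1])
    S = (S1 + S2) / 2.0
    return float(np.sqrt(d @ np.linalg.pinv(S) @ d))


def compare_cohorts_table(
    summaries_a: Iterable[CategoricalSummary],
    summaries_b: Iterable[CategoricalSummary],
) -> pd.DataFrame:
    """Side-by-side demographic table with one standardized difference per
    variable (repeated down that variable's block)."""
    rows = []
    for sa, sb in zip(summaries_a, summaries_b):
        if sa.variable != sb.variable or sa.categories != sb.categories:
            raise ValueError("summaries must pair the same variable and categories")
        if sa.total and sb.total:
            sd = standardized_difference(sa.proportions, sb.proportions)
        else:
            sd = float("nan")
        for cat, ca, pa, cb, pb in zip(
            sa.categories, sa.counts, sa.percents, sb.counts, sb.percents
        ):
            rows.append(
                {
                    "variable": sa.variable,
                    "category": cat,
                    "count_a": ca,
                    "pct_a": pa,
                    "count_b": cb,
                    "pct_b": pb,
                    "std_diff": sd,
                }
            )
    return pd.DataFrame(rows)
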