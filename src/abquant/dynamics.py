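"""Cohort-level statistics: trend testing, group comparison, outlier flagging."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "DEFAULT_Z_THRESHOLD",
    "DEFAULT_PHASE_EDGES",
    "DEFAULT_PHASE_LABELS",
    "CohortSeries",
    "TrendResult",
    "kendall_trend",
    "mann_whitney",
    "detect_outliers",
    "group_by_phase",
]

#: |z| above which a cohort measurement is flagged as an outlier.
DEFAULT_Z_THRESHOLD: float = 3.0

# Age-bin edges (months, right-inclusive) separating the accumulation
# phases: slow early rise, intermediate plateau (~6-8 mo), rapid growth
# (9-14 mo), late accumulation. Fully overridable.
DEFAULT_PHASE_EDGES: Tuple[float, ...] = (6.0, 9.0, 14.0)
DEFAULT_PHASE_LABELS: Tuple[str, ...] = ("early", "plateau", "growth", "late")


@dataclass(frozen=True)
class CohortSeries:
    """Per-animal measurements of one quantity across ages."""

    points: Tuple[Tuple[str, float, float], ...]  # (animal_id, age, value)
    label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "points", tuple(map(tuple, self.points)))
        for animal_id, age, value in self.points:
            if age <= 0:
                raise ValueError(f"age must be positive, got {age}")
            if not np.isfinite(value):
                raise ValueError(
                    f"non-finite value for animal {animal_id!r}"
                )

    @property
    def ages(self) -> np.ndarray:
        return np.array([p[1] for p in self.points])

    @property
    def values(self) -> np.ndarray:
        return np.array([p[2] for p in self.points])

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class TrendResult:
    tau: float
    p_value: float
    n: int
    removed_outliers: Tuple[str, ...] = ()

    def __post_init__(self):
        if abs(self.tau) > 1 + 1e-12:
            raise ValueError("|tau| must be <= 1")


def kendall_trend(
    series: CohortSeries,
    remove_outliers: bool = False,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
) -> TrendResult:
    """Kendall tau-b trend of value against age, with tie correction.

    The tau-b variant is used because cohort ages are heavily tied
    (several animals share each age). The two-sided p-value is exact for
    n <= 10 when there are no ties, and uses the normal approximation
    otherwise. Optionally removes |z| > ``z_threshold`` outliers (logged in
    the result) before testing.
    """
    if len(series) < 3:
        raise ValueError("kendall_trend requires n >= 3")
    points = list(series.points)
    removed: Tuple[str, ...] = ()
    if remove_outliers:
        flags = detect_outliers(
            [p[2] for p in points], z_threshold=z_threshold
        )
        removed = tuple(p[0] for p, f in zip(points, flags) if f)
        points = [p for p, f in zip(points, flags) if not f]
        if len(points) < 3:
            raise ValueError("fewer than 3 points left after outlier removal")
    ages = np.array([p[1] for p in points])
    values = np.array([p[2] for p in points])
    if np.ptp(values) == 0:
        raise ValueError("tau undefined: constant values")
    if np.ptp(ages) == 0:
        raise ValueError("tau undefined: constant ages")
    no_ties = (
        np.unique(ages).size == ages.size
        and np.unique(values).size == values.size
    )
    method = "exact" if (len(points) <= 10 and no_ties) else "asymptotic"
    result = stats.kendalltau(ages, values, variant="b", method=method)
    return TrendResult(
        tau=float(result.statistic),
        p_value=float(result.pvalue),
        n=len(points),
        removed_outliers=removed,
    )


def mann_whitney(
    group_a: Sequence[float], group_b: Sequence[float], alpha: float = 0.05
) -> Tuple[float, float, bool]:
    """Two-sided Mann-Whitney U test with tie correction.

    Returns ``(U, p, significant)`` where U counts pairs with a < b (ties
    counted 1/2), so identical groups give U = n_a * n_b / 2.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    result = stats.mannwhitneyu(a, b, alternative="two-sided")
    # scipy reports U1 = #(a > b) + ties/2; convert to the a < b orientation
    u_less = a.size * b.size - float(result.statistic)
    return u_less, float(result.pvalue), bool(result.pvalue < alpha)


def detect_outliers(
    values: Sequence[float], z_threshold: float = DEFAULT_Z_THRESHOLD
) -> np.ndarray:
    """Flag values whose |z| = |x - mean| / SD exceeds the threshold.

    Uses the population SD (ddof=0), under which the largest attainable |z|
    in a sample of size n is (n-1)/sqrt(n) — no flag is mathematically
    possible at z > 3 for n <= 10. A zero-SD input yields no flags with a
    warning.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("detect_outliers requires n >= 3")
    sd = x.std(ddof=0)
    if sd == 0:
        warnings.warn("zero standard deviation: no outliers flagged",
                      stacklevel=2)
        return np.zeros(x.size, dtype=bool)
    z = np.abs(x - x.mean()) / sd
    return z > z_threshold


def group_by_phase(
    ages: Sequence[float],
    edges: Sequence[float] = DEFAULT_PHASE_EDGES,
    labels: Sequence[str] = DEFAULT_PHASE_LABELS,
) -> List[str]:
    """Map each age to an accumulation-phase label via right-inclusive bins.

    With edges (e1, .., ek) and k+1 labels, age <= e1 gets the first label,
    e1 < age <= e2 the second, and age > ek the last.
    """
    edges = list(edges)
    labels = list(labels)
    if sorted(edges) != edges:
        raise ValueError("edges must be ascending")
    if len(labels) != len(edges) + 1:
        raise ValueError(
            f"need {len(edges) + 1} labels for {len(edges)} edges, "
            f"got {len(labels)}"
        )
    out = []
    for age in ages:
        if not np.isfinite(age) or age <= 0:
            raise ValueError(f"age outside all bins: {age}")
        index = int(np.searchsorted(edges, age, side="left"))
        out.append(labels[index])
    return out
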