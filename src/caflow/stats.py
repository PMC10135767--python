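"""Group-comparison layer: t-test, one-way ANOVA with Tukey HSD, and
boxplot-style summaries.

Two conditions are compared with Student's two-sample t-test
(pooled-variance by default, Welch behind a flag); three or more with
one-way ANOVA followed by Tukey's honestly-significant-difference test on
every unordered pair (studentized-range adjustment).  Summaries report the
five boxplot numbers (min, Q1, median, Q3, max; quartiles by linear
interpolation between order statistics) plus mean ± SEM.  P-values also
carry the usual star notation (ns, *, **, ***, ****).

A warning flag is attached whenever a group brings fewer than 15 values —
the assay's collection rule asks for at least 15 signaling events per
group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSample", "StatResult", "GroupSummary",
    "compare_two", "compare_many", "summarize", "significance_stars",
    "MIN_EVENTS_PER_GROUP",
]

MIN_EVENTS_PER_GROUP = 15


def significance_stars(p: float) -> str:
    """Star notation for a p-value: ns, *, **, ***, ****."""
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class GroupSample:
    """A condition label with its per-cell feature values."""

    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"group {self.label!r} has non-finite values")

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass
class StatResult:
    """Outcome of a group comparison."""

    test: str
    statistic: float
    p_value: float
    stars: str
    pairwise: pd.DataFrame | None = None     # Tukey table, all unordered pairs
    flags: tuple[str, ...] = ()


def _n15_flags(groups: list[GroupSample]) -> list[str]:
    return [f"n<{MIN_EVENTS_PER_GROUP}:{g.label}" for g in groups
            if g.n < MIN_EVENTS_PER_GROUP]


def compare_two(a: GroupSample, b: GroupSample,
                welch: bool = False) -> StatResult:
    """Two-sample t-test (Student pooled-variance; Welch optional).

    Two groups with zero variance and equal means are reported as
    t = 0, p = 1 with a ``zero_variance`` flag (no evidence of any
    difference, degenerate denominator).
    """
    for g in (a, b):
        if g.n < 2:
            raise ValueError(f"group {g.label!r} needs n >= 2")
    flags = _n15_flags([a, b])
    if a.values.var(ddof=1) == 0 and b.values.var(ddof=1) == 0:
        flags.append("zero_variance")
        if a.values.mean() == b.values.mean():
            return StatResult("t-test", 0.0, 1.0, "ns", flags=tuple(flags))
        return StatResult("t-test", float("inf"), 0.0, "****",
                          flags=tuple(flags))
    res = sps.ttest_ind(a.values, b.values, equal_var=not welch)
    p = float(res.pvalue)
    return StatResult("welch-t" if welch else "t-test",
                      float(res.statistic), p, significance_stars(p),
                      flags=tuple(flags))


def compare_many(groups: list[GroupSample], alpha: float = 0.05) -> StatResult:
    """One-way ANOVA with Tukey HSD pairwise comparisons.

    Requires at least three groups, each with n >= 2.  The pairwise table
    covers every unordered pair with the mean difference (a - b) and the
    studentized-range-adjusted p-value.
    """
    if len(groups) < 3:
        raise ValueError("compare_many needs at least 3 groups")
    for g in groups:
        if g.n < 2:
            raise ValueError(f"group {g.label!r} needs n >= 2")
    flags = _n15_flags(groups)
    values = [g.values for g in groups]
    f_res = sps.f_oneway(*values)
    tukey = sps.tukey_hsd(*values)
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            p_adj = float(tukey.pvalue[i, j])
            rows.append({
                "group_a": groups[i].label, "group_b": groups[j].label,
                "mean_diff": float(values[i].mean() - values[j].mean()),
                "p_adj": p_adj, "stars": significance_stars(p_adj),
                "significant": p_adj < alpha,
            })
    p = float(f_res.pvalue)
    return StatResult("anova+tukey", float(f_res.statistic), p,
                      significance_stars(p), pairwise=pd.DataFrame(rows),
                      flags=tuple(flags))


@dataclass
class GroupSummary:
    """Five-number boxplot summary plus mean ± SEM for one group."""

    label: str
    n: int
    minimum: float
    q1: float
    median: float
    q3: float
    maximum: float
    mean: float
    sem: float
    flags: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {"group": self.label, "n": self.n, "min": self.minimum,
                "q1": self.q1, "median": self.median, "q3": self.q3,
                "max": self.maximum, "mean": self.mean, "sem": self.sem,
                "flags": ";".join(self.flags)}


def summarize(group: GroupSample) -> GroupSummary:
    """Boxplot five-number summary (quartiles by linear interpolation
    between order statistics) with mean and SEM = SD/sqrt(n).

    A single-value group gets all five numbers equal, SEM 0 by convention,
    flagged ``single_value``.
    """
    if group.n < 1:
        raise ValueError("cannot summarize an empty group")
    v = group.values
    flags = []
    if group.n == 1:
        sem = 0.0
        flags.append("single_value")
    else:
        sem = float(v.std(ddof=1) / np.sqrt(group.n))
    if group.n < MIN_EVENTS_PER_GROUP:
        flags.append(f"n<{MIN_EVENTS_PER_GROUP}")
    q1, med, q3 = (float(q) for q in
                   np.quantile(v, [0.25, 0.5, 0.75], method="linear"))
    return GroupSummary(group.label, group.n, float(v.min()), q1, med, q3,
                        float(v.max()), float(v.mean()), sem,
                        flags=tuple(flags))
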