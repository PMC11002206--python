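"""Group summaries and hypothesis tests for sex x treatment cohorts.

Reporting conventions: endpoints are summarised as mean +/- SEM;
two-group contrasts use the unpaired pooled-variance (Student) t-test,
two-sided; multi-group contrasts use one-way ANOVA with Tukey HSD
post-hoc pairwise comparisons when the omnibus F is significant at
alpha = 0.05.  Significance stars follow the usual ladder:
* p <= 0.05, ** p <= 0.01, *** p <= 0.001, **** p <= 0.0001.  No
multiple-testing correction is applied across endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .errors import StatsError

__all__ = [
    "GroupSummary",
    "ComparisonResult",
    "summarize_group",
    "two_group_test",
    "oneway_anova",
    "significance_stars",
    "fold_change",
    "compare_endpoints",
]

#: p-value ladder, most extreme first.
_STAR_THRESHOLDS = (
    (0.0001, "****"),
    (0.001, "***"),
    (0.01, "**"),
    (0.05, "*"),
)


@dataclass(frozen=True)
class GroupSummary:
    """Mean +/- SEM for one group label."""

    label: str
    n: int
    mean: float
    sem: float


@dataclass(frozen=True)
class ComparisonResult:
    """A two-group t or multi-group F comparison with significance."""

    groups: tuple[str, ...]
    statistic: float  # t or F
    p_value: float
    stars: str
    kind: str  # "t" or "F"
    posthoc: Optional[pd.DataFrame] = None


def summarize_group(values: Sequence[float], label: str = "") -> GroupSummary:
    """Mean and standard error of the mean for one group."""
    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise StatsError("group summary needs at least one value")
    sem = float(np.std(v, ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0
    return GroupSummary(label=label, n=int(v.size), mean=float(np.mean(v)), sem=sem)


def significance_stars(p: float) -> str:
    """Map a p-value to its star label; p > 0.05 is 'ns'."""
    if not (0.0 <= p <= 1.0):
        raise StatsError(f"p-value must lie in [0, 1], got {p}")
    for threshold, label in _STAR_THRESHOLDS:
        if p <= threshold:
            return label
    return "ns"


def two_group_test(
    a: Sequence[float],
    b: Sequence[float],
    labels: tuple[str, str] = ("a", "b"),
) -> ComparisonResult:
    """Unpaired two-sided Student's t-test with pooled variance."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise StatsError(
            f"each group needs n >= 2 (got {a.size} and {b.size})"
        )
    t, p = stats.ttest_ind(a, b, equal_var=True)
    # identical groups give sd 0 -> nan; define t=0, p=1 for that edge
    if np.isnan(t):
        t, p = 0.0, 1.0
    return ComparisonResult(groups=labels, statistic=float(t),
                            p_value=float(p), stars=significance_stars(float(p)),
                            kind="t")


def oneway_anova(
    groups: Sequence[Sequence[float]],
    labels: Optional[Sequence[str]] = None,
    alpha: float = 0.05,
    posthoc: str = "tukey",
) -> ComparisonResult:
    """One-way ANOVA across >= 2 groups, with Tukey HSD post-hoc.

    The pairwise table is attached only when the omnibus test is
    significant at ``alpha``.  ``posthoc='pairwise_t'`` swaps Tukey for
    uncorrected pairwise Student t-tests.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise StatsError("ANOVA needs at least 2 groups")
    for g in arrays:
        if g.size < 2:
            raise StatsError("every ANOVA group needs n >= 2")
    if labels is None:
        labels = [f"g{i}" for i in range(len(arrays))]
    labels = tuple(str(l) for l in labels)

    f, p = stats.f_oneway(*arrays)
    if np.isnan(f):  # all groups identical and constant
        f, p = 0.0, 1.0
    table = None
    if p <= alpha:
        if posthoc == "tukey":
            values = np.concatenate(arrays)
            group_ids = np.concatenate(
                [np.repeat(lab, g.size) for lab, g in zip(labels, arrays)]
            )
            res = pairwise_tukeyhsd(values, group_ids, alpha=alpha)
            table = pd.DataFrame(
                res.summary().data[1:], columns=res.summary().data[0]
            )
        elif posthoc == "pairwise_t":
            rows = []
            for i in range(len(arrays)):
                for j in range(i + 1, len(arrays)):
                    r = two_group_test(arrays[i], arrays[j],
                                       labels=(labels[i], labels[j]))
                    rows.append({"group1": labels[i], "group2": labels[j],
                                 "t": r.statistic, "p": r.p_value,
                                 "stars": r.stars})
            table = pd.DataFrame(rows)
        else:
            raise StatsError(f"unknown posthoc method {posthoc!r}")
    return ComparisonResult(groups=labels, statistic=float(f),
                            p_value=float(p), stars=significance_stars(float(p)),
                            kind="F", posthoc=table)


def fold_change(treated_mean: float, control_mean: float) -> float:
    """Ratio of treated to control group means."""
    if control_mean <= 0:
        raise StatsError(
            f"fold change undefined for control mean {control_mean} <= 0"
        )
    return treated_mean / control_mean


def compare_endpoints(
    endpoints: pd.DataFrame,
    group_column: str = "group",
    contrasts: Optional[Sequence[tuple[str, str]]] = None,
    value_columns: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Run the paper-style comparison table over a tidy endpoint table.

    For every endpoint column and every requested two-group contrast,
    performs the Student t-test and reports group means, SEMs, fold
    change, t, p and stars.  When ``contrasts`` is None, all pairwise
    group contrasts are tested.
    """
    if group_column not in endpoints.columns:
        raise StatsError(f"no {group_column!r} column in endpoint table")
    groups = list(pd.unique(endpoints[group_column]))
    if contrasts is None:
        contrasts = [(a, b) for i, a in enumerate(groups) for b in groups[i + 1:]]
    if value_columns is None:
        value_columns = [
            c for c in endpoints.columns
            if c != group_column and pd.api.types.is_numeric_dtype(endpoints[c])
        ]
    rows = []
    for col in value_columns:
        for g1, g2 in contrasts:
            v1 = endpoints.loc[endpoints[group_column] == g1, col].dropna()
            v2 = endpoints.loc[endpoints[group_column] == g2, col].dropna()
            if v1.size < 2 or v2.size < 2:
                continue
            res = two_group_test(v1, v2, labels=(g1, g2))
            s1, s2 = summarize_group(v1, g1), summarize_group(v2, g2)
            rows.append({
                "endpoint": col, "group1": g1, "group2": g2,
                "n1": s1.n, "n2": s2.n,
                "mean1": s1.mean, "sem1": s1.sem,
                "mean2": s2.mean, "sem2": s2.sem,
                "fold_change_2_vs_1": (s2.mean / s1.mean if s1.mean > 0
                                       else np.nan),
                "t": res.statistic, "p": res.p_value, "stars": res.stars,
            })
    return pd.DataFrame(rows)
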