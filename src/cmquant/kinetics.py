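"""Differentiation-onset kinetics and two-group statistics.

During monolayer cardiac differentiation, each well of a plate is scored
daily (from day 7) for the first appearance of spontaneous beating. This
module summarizes such well-onset tables the way differentiation-efficiency
figures are built — daily new-onset percentage of seeded wells (mean +/- SEM
across biological replicates) and cumulative beating-well counts stacked by
replicate — and provides the two statistics used on beating-frequency
distributions: the unpaired two-tailed Student's t-test (pooled variance)
and a two-tailed F-test for equality of variances.

An onset table has one row per (replicate, well) with columns
``replicate, group, well, onset_day``; wells that never beat carry a missing
``onset_day`` and count in percentage denominators but never in cumulative
counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

__all__ = [
    "TTestResult",
    "VarianceTestResult",
    "validate_onset_table",
    "daily_onset_percent",
    "cumulative_beating",
    "ttest_unpaired",
    "variance_f_test",
]

DEFAULT_DAY_RANGE = (7, 17)


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float


@dataclass(frozen=True)
class VarianceTestResult:
    F: float
    df1: int
    df2: int
    p: float


def validate_onset_table(
    table: pd.DataFrame, day_range: tuple[int, int] = DEFAULT_DAY_RANGE
) -> pd.DataFrame:
    """Check and normalize an onset table.

    Requires columns ``replicate, group, well, onset_day``; rejects duplicate
    (replicate, well) rows and onset days outside ``day_range``. Returns a
    copy with ``onset_day`` as nullable integers.
    """
    required = {"replicate", "group", "well", "onset_day"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"onset table missing columns: {sorted(missing)}")
    out = table.copy()
    dup = out.duplicated(subset=["replicate", "well"])
    if dup.any():
        bad = out.loc[dup, ["replicate", "well"]].iloc[0]
        raise ValueError(
            f"duplicate (replicate, well) row: ({bad['replicate']!r}, {bad['well']!r})"
        )
    out["onset_day"] = pd.array(out["onset_day"], dtype="Int64")
    present = out["onset_day"].dropna()
    lo, hi = day_range
    if ((present < lo) | (present > hi)).any():
        raise ValueError(f"onset_day outside the observation range {day_range}")
    return out


def daily_onset_percent(
    table: pd.DataFrame,
    n_wells_per_replicate: int,
    day_range: tuple[int, int] = DEFAULT_DAY_RANGE,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Daily new-onset percentage of seeded wells, per replicate and summarized.

    Returns ``(per_replicate, summary)``: the first is tidy with columns
    ``group, day, replicate, new_onset_pct``; the second aggregates across
    replicates with ``mean_pct`` and ``sem_pct`` (SD over replicates divided
    by sqrt(n_replicates)).
    """
    table = validate_onset_table(table, day_range)
    if n_wells_per_replicate < 1:
        raise ValueError("n_wells_per_replicate must be >= 1")
    observed = table.groupby(["group", "replicate"], observed=True)["well"].count()
    if (observed > n_wells_per_replicate).any():
        raise ValueError("a replicate contains more wells than n_wells_per_replicate")
    days = np.arange(day_range[0], day_range[1] + 1)
    groups = sorted(table["group"].unique())
    rows = []
    for group in groups:
        sub = table[table["group"] == group]
        for rep in sorted(sub["replicate"].unique()):
            onsets = sub.loc[sub["replicate"] == rep, "onset_day"].dropna()
            counts = onsets.value_counts()
            for day in days:
                n_new = int(counts.get(day, 0))
                rows.append(
                    {
                        "group": group,
                        "day": int(day),
                        "replicate": rep,
                        "new_onset_pct": 100.0 * n_new / n_wells_per_replicate,
                    }
                )
    per_replicate = pd.DataFrame(rows)
    summary = (
        per_replicate.groupby(["group", "day"], observed=True)["new_onset_pct"]
        .agg(
            mean_pct="mean",
            sem_pct=lambda v: (v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0,
        )
        .reset_index()
    )
    return per_replicate, summary


def cumulative_beating(
    table: pd.DataFrame, day_range: tuple[int, int] = DEFAULT_DAY_RANGE
) -> pd.DataFrame:
    """Cumulative beating-well counts per day, stacked by replicate.

    Tidy output with columns ``group, day, replicate, cumulative_count`` plus
    a per-(group, day) ``total`` column (sum over replicates). Counts are
    monotone non-decreasing in day; never-beating wells are excluded.
    """
    table = validate_onset_table(table, day_range)
    days = np.arange(day_range[0], day_range[1] + 1)
    rows = []
    for group in sorted(table["group"].unique()):
        sub = table[table["group"] == group]
        for rep in sorted(sub["replicate"].unique()):
            onsets = sub.loc[sub["replicate"] == rep, "onset_day"].dropna().to_numpy()
            for day in days:
                rows.append(
                    {
                        "group": group,
                        "day": int(day),
                        "replicate": rep,
                        "cumulative_count": int(np.sum(onsets <= day)),
                    }
                )
    out = pd.DataFrame(rows)
    if out.empty:
        return pd.DataFrame(
            columns=["group", "day", "replicate", "cumulative_count", "total"]
        )
    totals = (
        out.groupby(["group", "day"], observed=True)["cumulative_count"]
        .sum()
        .rename("total")
    )
    return out.join(totals, on=["group", "day"])


def ttest_unpaired(x: Sequence[float], y: Sequence[float]) -> TTestResult:
    """Unpaired two-tailed Student's t-test with pooled variance.

    Degenerate inputs: zero pooled variance with equal means gives
    ``t = 0, p = 1``; zero pooled variance with unequal means is an error
    (the statistic is undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    df = x.size + y.size - 2
    pooled = ((x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1)) / df
    if pooled == 0:
        if x.mean() == y.mean():
            return TTestResult(t=0.0, df=df, p=1.0)
        raise ValueError("zero pooled variance with unequal means: t undefined")
    res = _stats.ttest_ind(x, y, equal_var=True)
    return TTestResult(t=float(res.statistic), df=df, p=float(res.pvalue))


def variance_f_test(x: Sequence[float], y: Sequence[float]) -> VarianceTestResult:
    """Two-tailed F-test for equality of variances.

    ``F = s2_x / s2_y`` (sample variances, n-1 denominators), degrees of
    freedom ``(n_x - 1, n_y - 1)``; the two-tailed p doubles the smaller tail
    probability and is capped at 1. Invariant under exchanging the samples.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    s2x = x.var(ddof=1)
    s2y = y.var(ddof=1)
    if s2x == 0 or s2y == 0:
        raise ValueError("F-test requires both sample variances to be positive")
    F = s2x / s2y
    df1, df2 = x.size - 1, y.size - 1
    lower = _stats.f.cdf(F, df1, df2)
    upper = _stats.f.sf(F, df1, df2)
    p = min(1.0, 2.0 * min(lower, upper))
    return VarianceTestResult(F=float(F), df1=df1, df2=df2, p=float(p))
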