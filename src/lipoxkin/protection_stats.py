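"""Membrane-protection effect statistics from grouped endpoint data.

Endpoints (hemolysis %, K+ efflux, TBARS) are summarized per group as
mean / SEM / n.  Effects relative to the oxidative-stressor group are
expressed as percent reduction, Cohen's d computed from the summary
statistics (SEM -> SD via sd = sem * sqrt(n); pooled SD as the
equal-n two-group form sqrt((sd_a^2 + sd_b^2)/2)), and t-based 95%
confidence intervals (df = n - 1).  Descriptive effect measures only;
no hypothesis testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from scipy import stats as _st


class StatsError(ValueError):
    """Invalid input to a summary-statistics operation."""


@dataclass(frozen=True)
class GroupSummary:
    mean: float
    sem: float
    n: int

    def __post_init__(self) -> None:
        if self.sem < 0:
            raise StatsError(f"sem must be >= 0, got {self.sem!r}")
        if self.n < 1:
            raise StatsError(f"n must be >= 1, got {self.n!r}")

    @property
    def sd(self) -> float:
        return self.sem * math.sqrt(self.n)


@dataclass(frozen=True)
class EffectResult:
    group: str
    summary: GroupSummary
    percent_change: float
    cohens_d: float
    ci95: tuple[float, float]


def percent_reduction(treated: GroupSummary, stressor: GroupSummary) -> float:
    """Percent reduction of the endpoint relative to the stressor
    group: 100 (stressor - treated) / stressor."""
    if stressor.mean == 0:
        raise StatsError("stressor mean is zero; percent reduction undefined")
    return 100.0 * (stressor.mean - treated.mean) / stressor.mean


def cohens_d(a: GroupSummary, b: GroupSummary) -> float:
    """Cohen's d between two groups from summary statistics.

    (mean_a - mean_b) / sqrt((sd_a^2 + sd_b^2)/2); with equal n this
    equals the df-weighted pooled-SD form.
    """
    if a.n < 2 or b.n < 2:
        raise StatsError("Cohen's d needs n >= 2 per group")
    pooled = math.sqrt((a.sd**2 + b.sd**2) / 2.0)
    diff = a.mean - b.mean
    if pooled == 0:
        if diff == 0:
            return 0.0
        raise StatsError("pooled SD is zero with unequal means: infinite effect")
    return diff / pooled


def ci95(g: GroupSummary) -> tuple[float, float]:
    """t-based 95% confidence interval for a group mean:
    mean +/- t(0.975, n-1) * sem."""
    if g.n < 2:
        raise StatsError("confidence interval needs n >= 2")
    half = _st.t.ppf(0.975, g.n - 1) * g.sem
    return (g.mean - half, g.mean + half)


def summarize_endpoint(
    table: pd.DataFrame, stressor_label: str, control_label: str | None = None
) -> pd.DataFrame:
    """Per-group effect table from a tidy replicate table.

    ``table`` needs columns group / replicate / value.  Each group is
    summarized (mean, SEM, n) and compared against the stressor
    group: percent reduction, Cohen's d, and its own 95% CI.  Returns
    a DataFrame with one row per group (stressor included, with zero
    percent change and d against itself).
    """
    required = {"group", "value"}
    if not required.issubset(table.columns):
        raise StatsError(f"table must have columns {sorted(required)}")
    groups = {}
    for name, sub in table.groupby("group", sort=False):
        vals = sub["value"].to_numpy(dtype=float)
        if vals.size < 2:
            raise StatsError(f"group {name!r} has < 2 replicates")
        groups[name] = GroupSummary(
            mean=float(vals.mean()),
            sem=float(vals.std(ddof=1) / math.sqrt(vals.size)),
            n=int(vals.size),
        )
    if stressor_label not in groups:
        raise StatsError(f"stressor group {stressor_label!r} not in table")
    stressor = groups[stressor_label]
    rows = []
    for name, g in groups.items():
        lo, hi = ci95(g)
        rows.append({
            "group": name,
            "mean": g.mean,
            "sem": g.sem,
            "n": g.n,
            "pct_reduction": percent_reduction(g, stressor),
            "cohens_d": cohens_d(g, stressor),
            "ci_lo": lo,
            "ci_hi": hi,
        })
    return pd.DataFrame(rows)
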