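"""Group comparisons: one-way ANOVA, t-based confidence intervals, star labels.

Mirrors how figure panels in patch-lifetime and cortex-intensity studies are
annotated: an omnibus fixed-effects one-way ANOVA across conditions, per-group
mean ± 95% CI error bars, and the conventional significance-star ladder.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["StatsResult", "one_way_anova", "mean_ci", "star_label"]


@dataclass
class StatsResult:
    """Outcome of a one-way ANOVA plus per-group summaries."""

    F: float
    df_between: int
    df_within: int
    p: float
    star: str
    degenerate: bool = False  # zero within-group variance with unequal means
    group_summary: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "F": self.F,
                    "df_between": self.df_between,
                    "df_within": self.df_within,
                    "p": self.p,
                    "star": self.star,
                    "degenerate": self.degenerate,
                }
            ]
        )


def _as_groups(groups) -> tuple[list[str], list[np.ndarray]]:
    if isinstance(groups, dict):
        labels = list(groups.keys())
        vals = [np.asarray(v, dtype=float).ravel() for v in groups.values()]
    else:
        labels = [f"group{i}" for i in range(len(groups))]
        vals = [np.asarray(v, dtype=float).ravel() for v in groups]
    return labels, vals


def one_way_anova(groups) -> StatsResult:
    """Classical fixed-effects one-way ANOVA.

    ``groups`` is a dict label -> observations or a list of observation
    vectors (k ≥ 2 groups, each n ≥ 2).  F = MS_between / MS_within with
    df = (k − 1, N − k); p is the F-distribution upper tail.  When the
    within-group variance is exactly zero and the means differ, the result
    is flagged degenerate with p = 0 and F = inf.
    """
    labels, vals = _as_groups(groups)
    k = len(vals)
    if k < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    if any(len(v) < 2 for v in vals):
        raise ValueError("each group needs at least 2 observations")
    N = sum(len(v) for v in vals)
    grand = np.concatenate(vals).mean()
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in vals)
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in vals)
    dfb, dfw = k - 1, N - k
    summary = pd.DataFrame(
        {
            "group": labels,
            "n": [len(v) for v in vals],
            "mean": [v.mean() for v in vals],
            "ci95_halfwidth": [mean_ci(v)[1] for v in vals],
        }
    )
    if ss_within == 0.0:
        if ss_between == 0.0:
            return StatsResult(0.0, dfb, dfw, 1.0, "ns", False, summary)
        return StatsResult(float("inf"), dfb, dfw, 0.0, star_label(0.0), True, summary)
    F = (ss_between / dfb) / (ss_within / dfw)
    p = float(sps.f.sf(F, dfb, dfw))
    return StatsResult(float(F), dfb, dfw, p, star_label(p), False, summary)


def mean_ci(values, confidence: float = 0.95) -> tuple[float, float]:
    """Mean and t-based two-sided CI half-width. Needs n ≥ 2."""
    v = np.asarray(values, dtype=float).ravel()
    if len(v) < 2:
        raise ValueError("confidence interval needs at least 2 values")
    sem = v.std(ddof=1) / np.sqrt(len(v))
    half = float(sps.t.ppf(0.5 + confidence / 2, len(v) - 1) * sem)
    return float(v.mean()), half


def star_label(p: float) -> str:
    """Significance stars: **** < 1e-4 ≤ *** < 1e-3 ≤ ** < 0.01 ≤ * < 0.05 ≤ ns."""
    if not (0.0 <= p <= 1.0) or np.isnan(p):
        raise ValueError(f"p-value {p} outside [0, 1]")
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"
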