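"""Shared statistical utilities: ANOVA with effect size, box summaries,
one-tailed t-tests.  Quartiles use linear interpolation (type-7)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class GroupComparison:
    kind: str
    statistic: float
    p: float
    r2: float = None
    df: tuple = None


def one_way_anova(groups) -> GroupComparison:
    """One-way fixed-effects ANOVA with R² = SS_between / SS_total."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs at least 2 samples")
    f, p = sps.f_oneway(*groups)
    allv = np.concatenate(groups)
    grand = allv.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_total = ((allv - grand) ** 2).sum()
    r2 = 0.0 if ss_total == 0 else ss_between / ss_total
    if ss_total == 0:
        f, p = 0.0, 1.0
    k, n = len(groups), len(allv)
    return GroupComparison("one_way_anova", float(f), float(p), float(r2),
                           (k - 1, n - k))


def box_summary(samples) -> dict:
    """Median, quartiles and 1.5·IQR whiskers (most extreme data within
    the fences), as drawn on the summary box plots."""
    x = np.asarray(samples, dtype=float)
    if x.size < 1:
        raise ValueError("box_summary requires at least one sample")
    q25, med, q75 = np.percentile(x, [25, 50, 75])
    iqr = q75 - q25
    lo_fence, hi_fence = q25 - 1.5 * iqr, q75 + 1.5 * iqr
    inside = x[(x >= lo_fence) & (x <= hi_fence)]
    return {"median": float(med), "q25": float(q25), "q75": float(q75),
            "whisker_lo": float(inside.min()), "whisker_hi": float(inside.max())}


def _one_tailed(t, df, direction):
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    p = sps.t.sf(t, df) if direction == "greater" else sps.t.cdf(t, df)
    return float(p)


def paired_t_one_tailed(a, b, direction: str = "greater") -> GroupComparison:
    """One-tailed paired t-test on ``b − a`` in the stated direction."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if len(a) < 2:
        raise ValueError("need at least 2 pairs")
    d = b - a
    sd = d.std(ddof=1)
    if sd == 0 and d.mean() != 0:
        raise ValueError("zero variance in paired differences (infinite t)")
    if sd == 0:
        return GroupComparison("paired_t_one_tailed", 0.0, 0.5, df=(len(a) - 1,))
    t = d.mean() / (sd / np.sqrt(len(d)))
    return GroupComparison("paired_t_one_tailed", float(t),
                           _one_tailed(t, len(d) - 1, direction),
                           df=(len(d) - 1,))


def unpaired_t_one_tailed(a, b, direction: str = "greater") -> GroupComparison:
    """One-tailed two-sample (Welch) t-test on ``mean(b) − mean(a)``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 samples per group")
    res = sps.ttest_ind(b, a, equal_var=False)
    t = float(res.statistic)
    return GroupComparison("unpaired_t_one_tailed", t,
                           _one_tailed(t, float(res.df), direction),
                           df=(float(res.df),))
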