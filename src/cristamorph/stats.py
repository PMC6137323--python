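"""Two-group nonparametric comparison, as used in the figure legends:
Mann-Whitney tests at 95% confidence, reported per metric with group
summaries. No multiple-testing correction by default (matching per-metric
reporting practice); Holm adjustment is available for reuse.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "mann_whitney_u",
    "GroupSummary",
    "summarize_group",
    "GroupComparison",
    "compare_conditions",
]


def mann_whitney_u(a, b, alternative: str = "two-sided") -> tuple[float, float]:
    """Mann-Whitney U test; returns (U of sample ``a``, p-value).

    The p-value is exact (full permutation null) for tie-free samples with
    n1 + n2 <= 30, and a tie-corrected, continuity-corrected normal
    approximation otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size + b.size <= 30 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative=alternative, method=method,
                           use_continuity=True)
    return float(res.statistic), float(res.pvalue)


@dataclass
class GroupSummary:
    n: int
    mean: float
    sd: float      # n-1 sample SD; NaN for n = 1
    sem: float     # sd / sqrt(n); NaN for n = 1
    min: float
    max: float


def summarize_group(values) -> GroupSummary:
    """n, mean, SD (n-1), SEM, min, max of one sample (NaNs dropped)."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 1:
        raise ValueError("need at least one finite value")
    sd = float(np.std(v, ddof=1)) if v.size > 1 else float("nan")
    sem = sd / math.sqrt(v.size) if v.size > 1 else float("nan")
    return GroupSummary(int(v.size), float(np.mean(v)), sd, sem,
                        float(v.min()), float(v.max()))


@dataclass
class GroupComparison:
    metric: str
    unit: str                  # sample unit: "crista" | "mitochondrion" | ""
    control: GroupSummary
    patient: GroupSummary
    u_statistic: float         # U for the control sample
    p_value: float
    p_adjusted: float | None   # Holm-adjusted p (None unless requested)
    alpha: float
    significant: bool          # p (adjusted if present) < alpha
    direction: str             # "patient_higher" | "patient_lower" | "none"


def _holm(pvals: list[float]) -> list[float]:
    order = np.argsort(pvals)
    m = len(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * pvals[i])
        adj[i] = min(running, 1.0)
    return adj.tolist()


def compare_conditions(
    control: pd.DataFrame,
    patient: pd.DataFrame,
    metrics: list[str] | None = None,
    units: dict[str, str] | None = None,
    alpha: float = 0.05,
    holm: bool = False,
) -> list[GroupComparison]:
    """One Mann-Whitney comparison per shared metric column.

    ``control`` and ``patient`` hold one row per sample unit (crista or
    mitochondrion) and must share the metric columns; a mismatch raises with
    the offending names.
    """
    if metrics is None:
        metrics = [c for c in control.columns
                   if c in patient.columns and pd.api.types.is_numeric_dtype(control[c])]
        missing = ([c for c in control.columns if c not in patient.columns]
                   + [c for c in patient.columns if c not in control.columns])
        if missing:
            raise ValueError(f"tables do not share columns: {sorted(set(missing))}")
    else:
        missing = [c for c in metrics if c not in control.columns or c not in patient.columns]
        if missing:
            raise ValueError(f"metric columns absent from a table: {missing}")

    comparisons: list[GroupComparison] = []
    pvals: list[float] = []
    for m in metrics:
        a = control[m].to_numpy(dtype=float)
        b = patient[m].to_numpy(dtype=float)
        a = a[np.isfinite(a)]
        b = b[np.isfinite(b)]
        u, p = mann_whitney_u(a, b)
        sa, sb = summarize_group(a), summarize_group(b)
        if sb.mean > sa.mean:
            direction = "patient_higher"
        elif sb.mean < sa.mean:
            direction = "patient_lower"
        else:
            direction = "none"
        comparisons.append(GroupComparison(
            metric=m, unit=(units or {}).get(m, ""), control=sa, patient=sb,
            u_statistic=u, p_value=p, p_adjusted=None, alpha=alpha,
            significant=p < alpha, direction=direction,
        ))
        pvals.append(p)
    if holm:
        for comp, padj in zip(comparisons, _holm(pvals)):
            comp.p_adjusted = padj
            comp.significant = padj < alpha
    return comparisons
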