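"""Two-group comparisons of per-implantation-site metrics.

The per-site value is the unit of comparison; groups are compared with the
two-tailed Mann-Whitney U-test.  The exact null distribution is used for
small tie-free samples (n*m <= 400), otherwise the normal approximation
with midranks, tie-corrected variance and continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

#: metrics extractable from a SiteReport
COHORT_METRICS = (
    "mean_diameter_um",
    "mean_segment_length_um",
    "length_to_diameter_ratio",
    "n_segments",
    "total_length_um",
    "conductance",
)


@dataclass
class GroupComparison:
    metric: str
    group_a: list
    group_b: list
    u_statistic: float
    p_value: float
    method: str  # "exact" | "normal-approximation"

    def __post_init__(self):
        nm = len(self.group_a) * len(self.group_b)
        if not 0 <= self.u_statistic <= nm:
            raise ValueError(f"U={self.u_statistic} outside [0, {nm}]")
        if not 0 < self.p_value <= 1:
            raise ValueError(f"p={self.p_value} outside (0, 1]")


def mann_whitney_u(x, y, alternative: str = "two-sided") -> GroupComparison:
    """Mann-Whitney U-test of two independent samples.

    U is computed from rank sums with midranks for ties.  The p-value is
    exact (full null enumeration) when ``n*m <= 400`` and the pooled data
    is tie-free, otherwise a tie- and continuity-corrected normal
    approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    exact = (x.size * y.size <= 400) and not has_ties
    res = mannwhitneyu(
        x, y, alternative=alternative, method="exact" if exact else "asymptotic"
    )
    return GroupComparison(
        metric="",
        group_a=x.tolist(),
        group_b=y.tolist(),
        u_statistic=float(res.statistic),
        p_value=float(min(1.0, res.pvalue)),
        method="exact" if exact else "normal-approximation",
    )


def extract_metric(report, metric: str) -> float:
    if metric == "conductance":
        return report.flow.conductance
    if metric in COHORT_METRICS:
        return getattr(report.summary, metric)
    raise ValueError(
        f"unknown metric {metric!r}; available metrics: {', '.join(COHORT_METRICS)}"
    )


def compare_cohort(reports_a, reports_b, metrics=None):
    """One Mann-Whitney comparison per metric, per-site values as the unit.

    Returns ``(comparisons, table)`` where ``table`` is a tidy DataFrame of
    per-site metric values with group labels.
    """
    if not reports_a or not reports_b:
        raise ValueError("both groups need at least one site report")
    metrics = list(
        metrics
        if metrics is not None
        else (
            "mean_diameter_um",
            "mean_segment_length_um",
            "length_to_diameter_ratio",
            "conductance",
        )
    )
    comparisons = []
    rows = []
    for metric in metrics:
        a = [extract_metric(r, metric) for r in reports_a]
        b = [extract_metric(r, metric) for r in reports_b]
        cmp = mann_whitney_u(a, b)
        cmp.metric = metric
        comparisons.append(cmp)
    for group, reports in (("A", reports_a), ("B", reports_b)):
        for r in reports:
            row = {"group": group, "site_id": r.site_id}
            for metric in metrics:
                row[metric] = extract_metric(r, metric)
            rows.append(row)
    return comparisons, pd.DataFrame(rows)
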