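"""Group-level statistics and viability arithmetic.

Conventions follow the study design these analyses serve: viability over
replicate cultures is summarised as mean ± SEM, calcium-activity and
network metrics as median with (Q1, Q3); two-group comparisons use the
Mann-Whitney U test (exact for small untied samples), multi-group
comparisons use one-way ANOVA with Tukey's HSD post hoc.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateVarianceError

__all__ = [
    "GroupSummary",
    "viability_percent",
    "median_iqr",
    "mean_sem",
    "mann_whitney",
    "anova_tukey",
    "fold_change",
]

#: exact Mann-Whitney enumeration is used up to this combined sample size
EXACT_MW_MAX_N = 12


@dataclass(frozen=True)
class GroupSummary:
    group_label: str
    n: int
    center: float             # mean or median, per the metric's convention
    spread: tuple[float, float]  # (−SEM, +SEM) or (Q1, Q3)
    kind: str                 # "mean_sem" | "median_iqr"


def viability_percent(dead_count: int, total_count: int) -> float:
    """Viability = 100·(1 − dead/total), to 2 decimals."""
    if total_count < 1:
        raise ValueError("total_count must be >= 1")
    if dead_count < 0 or dead_count > total_count:
        raise ValueError(
            f"dead_count must be in [0, total_count], got {dead_count}/{total_count}")
    return round(100.0 * (1.0 - dead_count / total_count), 2)


def median_iqr(values, group_label: str = "") -> GroupSummary:
    """Median and (Q1, Q3) by the linear-interpolation quantile convention."""
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("median_iqr of an empty collection")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return GroupSummary(group_label=group_label, n=int(v.size),
                        center=float(med), spread=(float(q1), float(q3)),
                        kind="median_iqr")


def mean_sem(values, group_label: str = "") -> GroupSummary:
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("mean_sem of an empty collection")
    sem = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0
    return GroupSummary(group_label=group_label, n=int(v.size),
                        center=float(v.mean()), spread=(sem, sem),
                        kind="mean_sem")


def mann_whitney(group_a, group_b) -> tuple[float, float]:
    """Mann-Whitney U (for group_a) and two-sided p.

    Exact enumeration when the combined sample size is ≤ 12 and there are
    no ties; tie-corrected normal approximation (with continuity
    correction) otherwise.  Two identical all-tied samples give p = 1.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return a.size * b.size / 2.0, 1.0
    has_ties = len(np.unique(pooled)) < pooled.size
    if not has_ties and pooled.size <= EXACT_MW_MAX_N:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided",
                               method="asymptotic", use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def anova_tukey(groups: dict[str, np.ndarray]) -> tuple[float, float, pd.DataFrame]:
    """One-way ANOVA F and p, plus a Tukey-HSD pairwise table.

    ``groups`` maps label → values (each n ≥ 2).  Returns
    ``(F, p, pairwise)`` where *pairwise* has columns ``group_a``,
    ``group_b``, ``diff``, ``p_adj`` (studentized-range adjusted).
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    labels = list(groups)
    arrays = [np.asarray(list(groups[k]), dtype=float) for k in labels]
    for k, v in zip(labels, arrays):
        if v.size < 2:
            raise ValueError(f"group {k} needs n >= 2")
    if all(np.all(v == v[0]) for v in arrays):
        raise DegenerateVarianceError(
            "zero within-group variance in every group; ANOVA undefined")
    f, p = sps.f_oneway(*arrays)
    tk = sps.tukey_hsd(*arrays)
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            rows.append((labels[i], labels[j],
                         float(arrays[i].mean() - arrays[j].mean()),
                         float(tk.pvalue[i, j])))
    pairwise = pd.DataFrame(rows, columns=["group_a", "group_b", "diff",
                                           "p_adj"])
    return float(f), float(p), pairwise


def anova_two_factor(data: pd.DataFrame, value: str, factor_a: str,
                     factor_b: str) -> pd.DataFrame:
    """Two-way ANOVA (type II) for a hypoxia × treatment factorisation.

    Thin wrapper over ``statsmodels``; exposed for designs where the two
    factors are explicit.  Returns the ANOVA table.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    model = ols(f"{value} ~ C({factor_a}) * C({factor_b})", data=data).fit()
    return sm.stats.anova_lm(model, typ=2)


def fold_change(metric_by_group: dict[str, float],
                baseline_group: str) -> dict[str, float]:
    """Ratio of each group's (median) value to the baseline group's."""
    base = metric_by_group[baseline_group]
    if base == 0:
        raise ZeroDivisionError(
            f"baseline group {baseline_group!r} has zero median; "
            "fold change undefined")
    return {k: v / base for k, v in metric_by_group.items()}
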