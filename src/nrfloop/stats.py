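"""The study's statistical procedures for grouped measurements.

Two procedures are exposed: independent two-sample Student's t tests
(pooled variance) with Bonferroni correction, and one-way fixed-effects
ANOVA with Tukey's HSD post hoc test (Tukey–Kramer for unbalanced
designs). Both use two-sided p-values and a 0.05 significance level.
"""

from __future__ import annotations

from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["t_test_bonferroni", "anova_tukey"]

ALPHA = 0.05


def _check_groups(data: Mapping[str, Sequence[float]], min_groups: int = 2) -> None:
    if len(data) < min_groups:
        raise ValueError(f"need at least {min_groups} groups, got {len(data)}")
    for g, v in data.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")


def t_test_bonferroni(
    data: Mapping[str, Sequence[float]],
    comparisons: Sequence[tuple[str, str]] | None = None,
    welch: bool = False,
) -> pd.DataFrame:
    """Pairwise two-sample t tests with Bonferroni correction.

    Student's pooled-variance t by default (``welch=True`` switches to
    Welch). ``comparisons`` defaults to all pairs; the correction factor
    m is the number of comparisons performed.
    """
    _check_groups(data)
    if comparisons is None:
        comparisons = list(combinations(data.keys(), 2))
    m = len(comparisons)
    rows = []
    for g1, g2 in comparisons:
        x, y = np.asarray(data[g1], float), np.asarray(data[g2], float)
        res = sps.ttest_ind(x, y, equal_var=not welch)
        df = (
            len(x) + len(y) - 2
            if not welch
            else float(res.df) if hasattr(res, "df") else np.nan
        )
        p_raw = float(res.pvalue)
        p_adj = min(1.0, p_raw * m)
        rows.append(
            {
                "group1": g1,
                "group2": g2,
                "t": float(res.statistic),
                "df": df,
                "p_raw": p_raw,
                "p_adj": p_adj,
                "significant": p_adj < ALPHA,
            }
        )
    return pd.DataFrame(rows)


def anova_tukey(
    data: Mapping[str, Sequence[float]],
) -> tuple[float, int, int, float, pd.DataFrame]:
    """One-way ANOVA followed by Tukey's HSD.

    Returns ``(F, df_between, df_within, p, tukey_table)``. Degenerate
    input with zero within-group variance but unequal means yields
    ``F = inf, p = 0`` rather than an error.
    """
    _check_groups(data)
    groups = [np.asarray(v, float) for v in data.values()]
    labels = list(data.keys())
    k = len(groups)
    n = sum(len(g) for g in groups)
    df_b, df_w = k - 1, n - k

    grand = np.concatenate(groups).mean()
    ss_b = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_w = sum(((g - g.mean()) ** 2).sum() for g in groups)
    if ss_w == 0.0:
        if ss_b == 0.0:
            F, p = 0.0, 1.0
        else:
            F, p = np.inf, 0.0
    else:
        F = (ss_b / df_b) / (ss_w / df_w)
        p = float(sps.f.sf(F, df_b, df_w))

    if np.isfinite(F) and ss_w > 0:
        hsd = sps.tukey_hsd(*groups)
        ci = hsd.confidence_interval()
        rows = []
        for i, j in combinations(range(k), 2):
            rows.append(
                {
                    "group1": labels[i],
                    "group2": labels[j],
                    "diff": float(groups[i].mean() - groups[j].mean()),
                    "ci_low": float(ci.low[i, j]),
                    "ci_high": float(ci.high[i, j]),
                    "p_adj": float(hsd.pvalue[i, j]),
                    "significant": float(hsd.pvalue[i, j]) < ALPHA,
                }
            )
    else:
        rows = [
            {
                "group1": labels[i],
                "group2": labels[j],
                "diff": float(groups[i].mean() - groups[j].mean()),
                "ci_low": np.nan,
                "ci_high": np.nan,
                "p_adj": 1.0 if F == 0.0 else 0.0,
                "significant": F != 0.0,
            }
            for i, j in combinations(range(k), 2)
        ]
    return float(F), df_b, df_w, float(p), pd.DataFrame(rows)
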