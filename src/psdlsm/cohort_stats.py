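"""Sample-level statistics: Spearman correlations, one-way ANOVA, BH-FDR.

These are the checks that depression scores are not merely proxies for
stroke severity, age, sex or lesion size: rank correlations of every
depression score with each ordinal/continuous covariate, a one-way ANOVA
across sexes, and Benjamini-Hochberg false-discovery-rate correction over
the whole batch of tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties), t-approximation p."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation is undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value family")
    return multipletests(p, method="fdr_bh")[1]


def anova_by_group(scores, group) -> tuple[float, float]:
    """One-way ANOVA of scores across the levels of a grouping variable.

    With two groups (e.g. sex) the F statistic equals the square of the
    pooled two-sample t statistic.
    """
    scores, group = np.asarray(scores, float), np.asarray(group)
    levels = np.unique(group)
    if len(levels) < 2:
        raise ValueError("need at least two non-empty groups")
    samples = [scores[group == g] for g in levels]
    if any(len(s) == 0 for s in samples):
        raise ValueError("every group must be non-empty")
    f, p = stats.f_oneway(*samples)
    return float(f), float(p)


def correlation_report(
    table: pd.DataFrame,
    score_cols: list[str],
    covariate_cols: list[str],
    sex_col: str | None = "sex",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Batch report: every score vs every covariate, plus ANOVA by sex.

    One FDR family spans all tests in the batch (all Spearman pairs and
    the per-score sex ANOVAs).  Returns a tidy frame with raw and
    adjusted p-values and significance flags at ``alpha``.
    """
    rows = []
    for s in score_cols:
        for c in covariate_cols:
            rho, p = spearman(table[s], table[c])
            rows.append({"test": "spearman", "score": s, "covariate": c, "stat": rho, "p_raw": p})
        if sex_col is not None:
            f, p = anova_by_group(table[s], table[sex_col])
            rows.append({"test": "anova", "score": s, "covariate": sex_col, "stat": f, "p_raw": p})
    report = pd.DataFrame(rows)
    report["p_fdr"] = bh_fdr(report["p_raw"])
    report["significant"] = report["p_fdr"] < alpha
    return report
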