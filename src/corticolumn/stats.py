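"""Group-comparison inference used across the analyses.

One-way ANOVA followed by two-sided Tukey HSD over group pairs, with
Bonferroni multiplication across measurement families; exact (or
tie-corrected normal) two-sided Wilcoxon rank-sum; Spearman correlation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as ss

__all__ = ["groupwise_comparison", "wilcoxon_rank_sum", "spearman_correlation"]


def groupwise_comparison(measurements: pd.DataFrame) -> pd.DataFrame:
    """Per-family ANOVA + Tukey HSD + cross-family Bonferroni.

    ``measurements`` has columns ``value``, ``group`` and optionally
    ``family`` (one test family per figure panel).  Within each family a
    one-way ANOVA is computed, then Tukey's HSD (studentized-range
    distribution) over all group pairs; pairwise p-values are multiplied by
    the number of families and capped at 1.
    """
    df = measurements.copy()
    if "family" not in df.columns:
        df["family"] = "all"
    n_fam = df["family"].nunique()
    rows = []
    for fam, sub in df.groupby("family"):
        groups = {g: s["value"].to_numpy() for g, s in sub.groupby("group")}
        names = sorted(groups)
        if len(names) < 2:
            raise ValueError(f"family {fam!r} has fewer than 2 groups")
        if any(len(v) < 2 for v in groups.values()):
            raise ValueError("each group needs n >= 2")
        f_stat, f_p = ss.f_oneway(*[groups[g] for g in names])
        hsd = ss.tukey_hsd(*[groups[g] for g in names])
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                p_raw = float(hsd.pvalue[i, j])
                rows.append(
                    {
                        "family": fam,
                        "group_a": names[i],
                        "group_b": names[j],
                        "anova_F": float(f_stat),
                        "anova_p": float(f_p),
                        "p_raw": p_raw,
                        "p_adj": min(p_raw * n_fam, 1.0),
                    }
                )
    return pd.DataFrame(rows)


def wilcoxon_rank_sum(x, y, exact_below: int = 50) -> float:
    """Two-sided rank-sum p-value.

    Uses the exact permutation distribution of the rank sum when the pooled
    sample size is at most ``exact_below`` and there are no ties; otherwise
    the normal approximation with tie correction (and continuity
    correction).  Complete separation of samples of sizes 3 and 4 gives the
    minimal exact two-sided p = 2/35 ~ 0.0571.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= exact_below and not ties) else "asymptotic"
    return float(ss.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def spearman_correlation(x, y) -> float:
    """Spearman rank correlation (Pearson on average ranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size != x.size:
        raise ValueError("need equal-length inputs with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input")
    return float(ss.spearmanr(x, y).statistic)
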