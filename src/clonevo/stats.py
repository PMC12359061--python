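"""Thin statistical wrappers shared across analysis stages.

All two-group distribution comparisons in the pipeline go through the
Wilcoxon rank-sum (Mann-Whitney U) test — exact for small tie-free samples,
tie-corrected normal approximation otherwise — and proportion comparisons
through Fisher's exact test, matching the conventions of the analyses these
modules implement.
"""

from __future__ import annotations

import logging
import math

import numpy as np
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = ["rank_sum_test", "fisher_exact_2x2", "fisher_combined_p"]


def rank_sum_test(x, y, alternative: str = "two-sided") -> dict:
    """Tie-corrected Wilcoxon rank-sum test.

    Returns a dict with the Mann-Whitney U statistic (of *x* relative to
    *y*), the p-value, the difference of group medians, and the direction.
    Degenerate all-tied inputs give p = 1 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        logger.warning("rank-sum test on all-tied input; reporting p = 1")
        return {
            "statistic": x.size * y.size / 2.0,
            "p_value": 1.0,
            "median_difference": 0.0,
            "direction": "none",
        }
    res = sps.mannwhitneyu(x, y, alternative=alternative, method="auto")
    med_diff = float(np.median(x) - np.median(y))
    direction = "greater" if res.statistic > x.size * y.size / 2 else (
        "less" if res.statistic < x.size * y.size / 2 else "none"
    )
    return {
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "median_difference": med_diff,
        "direction": direction,
    }


def fisher_exact_2x2(table, alternative: str = "two-sided") -> dict:
    """Fisher's exact test on a 2x2 table.

    The odds ratio is the sample (conditional-free) odds ratio with a
    Haldane-Anscombe 0.5 correction applied when any cell is zero, so it
    stays finite for extreme tables; the p-value is the exact two-sided
    hypergeometric probability-mass test.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with non-negative counts")
    if t.sum(axis=1).min() == 0:
        empty = "first" if t[0].sum() == 0 else "second"
        raise ValueError(f"the {empty} group is empty; cannot form a 2x2 comparison")
    res = sps.fisher_exact(t, alternative=alternative)
    a, b, c, d = t.ravel().astype(float)
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return {
        "odds_ratio": a * d / (b * c),
        "p_value": float(res.pvalue),
    }


def fisher_combined_p(p_values) -> float:
    """Fisher's method for combining independent p-values."""
    p = np.asarray([v for v in p_values if np.isfinite(v)], dtype=float)
    if p.size == 0:
        return math.nan
    chi2 = -2.0 * np.sum(np.log(np.clip(p, 1e-300, 1.0)))
    return float(sps.chi2.sf(chi2, df=2 * p.size))
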