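"""Independent brute-force oracles used to verify the package's statistics.

These deliberately avoid the code paths they check: the rank-sum oracle
enumerates every group assignment, the Fisher oracle enumerates every table
with the observed margins, and the CCF oracle scans multiplicities and
recomputes the closed form directly.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy.stats import hypergeom


def exact_rank_sum_p(x, y, alternative: str = "two-sided") -> float:
    """Exact Mann-Whitney p by full enumeration of group assignments.

    Uses midranks, so it is exact for tied data too (the package's
    implementation switches to a tie-corrected normal approximation in that
    case — compare only on tie-free inputs).
    """
    x = list(map(float, x))
    y = list(map(float, y))
    pooled = np.array(x + y)
    n, m = len(x), len(y)
    order = pooled.argsort(kind="mergesort")
    ranks = np.empty(len(pooled))
    # midranks
    sorted_vals = pooled[order]
    i = 0
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    obs_u = ranks[:n].sum() - n * (n + 1) / 2

    us = []
    for idx in combinations(range(n + m), n):
        us.append(ranks[list(idx)].sum() - n * (n + 1) / 2)
    us = np.array(us)
    eps = 1e-9
    p_le = np.mean(us <= obs_u + eps)
    p_ge = np.mean(us >= obs_u - eps)
    if alternative == "less":
        return float(p_le)
    if alternative == "greater":
        return float(p_ge)
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def exact_fisher_p(table) -> float:
    """Two-sided Fisher p by hypergeometric enumeration over the margins."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    p_obs = hypergeom.pmf(a, n, r1, c1)
    p = 0.0
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        pk = hypergeom.pmf(k, n, r1, c1)
        if pk <= p_obs * (1 + 1e-7):
            p += pk
    return float(min(1.0, p))


def brute_force_ccf(vaf: float, purity: float, major_cn: int, minor_cn: int,
                    normal_cn: int = 2) -> tuple[int, float]:
    """Reference multiplicity choice and CCF via an explicit scan over m.

    Scans every m in {1..major_cn}, scores |expected clonal VAF - vaf|, and
    keeps the smallest best m; recomputes the CCF closed form from scratch.
    """
    cnt = major_cn + minor_cn
    denom = purity * cnt + (1 - purity) * normal_cn
    best_m, best_err = None, None
    for m in range(1, major_cn + 1):
        err = abs(m * purity / denom - vaf)
        if best_err is None or err < best_err - 1e-15:
            best_m, best_err = m, err
    ccf = vaf * denom / (purity * best_m)
    return best_m, min(ccf, 1.0)
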