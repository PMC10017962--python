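"""Group-comparison statistics and reporting columns.

For each dataset x task x biomarker cell the two groups (CN vs PD) are
compared with the Kruskal-Wallis H-test; p-values are corrected by
Benjamini-Hochberg within each biomarker family; the effect size is the
H-based eta-squared, eta2 = (H - k + 1)/(n - k); discriminability is the
tie-corrected AUROC reported orientation-free (max(A, 1-A)), with
directionality carried separately by the observed behavior (sign of the
PD-minus-CN median difference).  Severity correlations are Spearman rank
coefficients on PD subjects, FDR-corrected the same way.

The H-test and the BH step-up run through scipy/statsmodels, the same
routines practitioners use; an exact-permutation variant of the two-group
H-test is provided for validation at small n.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import scipy.stats
from statsmodels.stats.multitest import fdrcorrection

__all__ = [
    "kruskal_wallis",
    "kruskal_wallis_exact",
    "eta_squared_from_h",
    "auroc",
    "bh_adjust",
    "observed_behavior",
    "spearman",
    "ALPHA",
]

#: Family-wise significance level.
ALPHA = 0.05


def _check_groups(groups) -> list[np.ndarray]:
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValueError("need at least two groups")
    if any(len(a) == 0 for a in arrs):
        raise ValueError("empty group")
    return arrs


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected, mid-ranks) and chi-square p-value.

    All-tied input returns ``(0.0, 1.0)`` instead of failing: a completely
    degenerate biomarker is evidence of no group difference, not an error.
    """
    arrs = _check_groups(groups)
    if sum(map(len, arrs)) < 3:
        raise ValueError("need at least three observations in total")
    pooled = np.concatenate(arrs)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = scipy.stats.kruskal(*arrs)
    return float(h), float(p)


def _h_statistic(pooled: np.ndarray, sizes: list[int]) -> float:
    n = len(pooled)
    ranks = scipy.stats.rankdata(pooled)
    h = 0.0
    start = 0
    for sz in sizes:
        h += ranks[start : start + sz].sum() ** 2 / sz
        start += sz
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    return h / tie if tie > 0 else 0.0


def kruskal_wallis_exact(x, y) -> tuple[float, float]:
    """Two-group H with an exact permutation p-value (small n only).

    Enumerates all assignments of the pooled sample to the two group sizes;
    the p-value is the fraction of assignments whose H is >= the observed H
    (within numerical tolerance).  Intended for n <= ~8 per group.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty group")
    pooled = np.concatenate([x, y])
    n = len(pooled)
    if math.comb(n, len(x)) > 500_000:
        raise ValueError("sample too large for exact enumeration")
    h_obs = _h_statistic(pooled, [len(x), len(y)])
    count = 0
    total = 0
    idx = np.arange(n)
    for combo in itertools.combinations(idx, len(x)):
        mask = np.zeros(n, dtype=bool)
        mask[list(combo)] = True
        h = _h_statistic(np.concatenate([pooled[mask], pooled[~mask]]),
                         [len(x), len(y)])
        if h >= h_obs - 1e-12:
            count += 1
        total += 1
    return float(h_obs), count / total


def eta_squared_from_h(h: float, n: int, k: int = 2) -> float:
    """H-based eta-squared effect size, (H - k + 1)/(n - k), floored at 0."""
    if n <= k:
        raise ValueError("total sample size must exceed the number of groups")
    return max(0.0, (h - k + 1) / (n - k))


def auroc(cn, pd, directed: bool = False) -> float:
    """Tie-corrected AUROC between two samples.

    The directed value is A = P(pd > cn) + P(pd = cn)/2, computed from
    mid-ranks.  By default the orientation-free value max(A, 1 - A) is
    returned, so reported AUROCs are always >= 0.5 and the direction of the
    difference is carried by :func:`observed_behavior`.
    """
    cn = np.asarray(cn, dtype=float)
    pd_ = np.asarray(pd, dtype=float)
    if len(cn) == 0 or len(pd_) == 0:
        raise ValueError("empty group")
    ranks = scipy.stats.rankdata(np.concatenate([cn, pd_]))
    r_pd = ranks[len(cn) :].sum()
    u = r_pd - len(pd_) * (len(pd_) + 1) / 2.0
    a = u / (len(cn) * len(pd_))
    return float(a if directed else max(a, 1.0 - a))


def bh_adjust(pvalues, alpha: float = ALPHA) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up within one family.

    Returns (adjusted p-values, rejection flags at ``alpha``).  Adjusted
    p-values are monotone (cumulative minimum from the largest rank).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj = fdrcorrection(p, alpha=alpha, method="indep")
    return p_adj, reject


def observed_behavior(cn, pd) -> str:
    """Direction of the PD median relative to CN: 'up', 'down' or 'tie'."""
    cn = np.asarray(cn, dtype=float)
    pd_ = np.asarray(pd, dtype=float)
    if len(cn) == 0 or len(pd_) == 0:
        raise ValueError("empty group")
    diff = float(np.median(pd_) - np.median(cn))
    if diff > 0:
        return "up"
    if diff < 0:
        return "down"
    return "tie"


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (mid-ranks) with its p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need at least three paired observations")
    rho, p = scipy.stats.spearmanr(x, y)
    if np.isnan(rho):  # a constant input has no rank ordering
        return float("nan"), float("nan")
    return float(rho), float(p)
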