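"""Rank statistics used by the association engine.

The default p-values use the classic large-sample approximations
(Student-t for Spearman, tie-corrected normal for Mann-Whitney and
Wilcoxon), matching common statistical software.  Exact enumeration and
seeded Monte-Carlo permutation modes exist primarily so the
approximations can be checked against independent oracles.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "RankTestResult",
    "spearman",
    "mann_whitney",
    "wilcoxon_signed_rank",
    "bonferroni",
]


@dataclass
class RankTestResult:
    """Statistic, two-sided p-value and degeneracy flags."""

    statistic: float
    p: float
    flags: tuple[str, ...] = ()


def _spearman_rho(rx: np.ndarray, ry: np.ndarray) -> float:
    """Pearson correlation of mid-ranks (tie-corrected Spearman rho)."""
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt((rx**2).sum() * (ry**2).sum())
    if denom == 0:
        return math.nan
    return float((rx * ry).sum() / denom)


def spearman(
    x,
    y,
    method: str = "approx",
    n_perm: int = 9999,
    seed: int | None = None,
) -> RankTestResult:
    """Spearman rank correlation with a two-sided p-value.

    Pairs containing NaN are dropped.  ``approx`` uses the t
    approximation with n-2 df; ``exact`` enumerates all rank
    permutations (n <= 8); ``permutation`` draws ``n_perm`` seeded
    shuffles.  Zero rank variance in either vector yields a NaN rho
    flagged ``zero_variance`` (reported not-significant downstream).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be aligned 1-d vectors")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 4:
        raise ValueError(f"need at least 4 complete pairs, got {n}")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = _spearman_rho(rx, ry)
    if math.isnan(rho):
        return RankTestResult(math.nan, math.nan, ("zero_variance",))

    if method == "approx":
        if abs(rho) >= 1.0:
            # monotone identity/reversal: smallest representable tail
            return RankTestResult(rho, float(np.nextafter(0, 1)))
        t = rho * math.sqrt((n - 2) / (1 - rho * rho))
        p = 2.0 * float(sps.t.sf(abs(t), df=n - 2))
        return RankTestResult(rho, min(1.0, p))

    if method == "exact":
        if n > 8:
            raise ValueError("exact Spearman enumeration limited to n <= 8")
        count = 0
        total = 0
        target = abs(rho) - 1e-12
        for perm in itertools.permutations(ry):
            total += 1
            if abs(_spearman_rho(rx, np.array(perm))) >= target:
                count += 1
        return RankTestResult(rho, count / total)

    if method == "permutation":
        rng = np.random.default_rng(seed)
        count = 0
        target = abs(rho) - 1e-12
        ry_work = ry.copy()
        for _ in range(n_perm):
            rng.shuffle(ry_work)
            if abs(_spearman_rho(rx, ry_work)) >= target:
                count += 1
        return RankTestResult(rho, (count + 1) / (n_perm + 1))

    raise ValueError(f"unknown method {method!r}")


def _mw_u(pooled_ranks: np.ndarray, idx_x, n1: int) -> float:
    return float(pooled_ranks[list(idx_x)].sum() - n1 * (n1 + 1) / 2)


def mann_whitney(x, y, method: str = "auto") -> RankTestResult:
    """Two-sided Mann-Whitney U test between independent samples.

    Exact enumeration of all label arrangements when both groups have
    n <= 10 and the pooled data are tie-free; otherwise a tie-corrected
    normal approximation (no continuity correction).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u_obs = _mw_u(ranks, range(n1), n1)

    has_ties = len(np.unique(pooled)) < n1 + n2
    use_exact = method == "exact" or (
        method == "auto" and n1 <= 10 and n2 <= 10 and not has_ties
    )
    if use_exact:
        us = np.array(
            [
                _mw_u(ranks, idx, n1)
                for idx in itertools.combinations(range(n1 + n2), n1)
            ]
        )
        lo = float((us <= u_obs + 1e-12).mean())
        hi = float((us >= u_obs - 1e-12).mean())
        return RankTestResult(u_obs, min(1.0, 2.0 * min(lo, hi)))

    mean_u = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    n = n1 + n2
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    var_u = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var_u == 0:
        return RankTestResult(u_obs, 1.0, ("zero_variance",))
    z = (u_obs - mean_u) / math.sqrt(var_u)
    p = 2.0 * float(sps.norm.sf(abs(z)))
    return RankTestResult(u_obs, min(1.0, p))


def wilcoxon_signed_rank(x, y=None, method: str = "auto") -> RankTestResult:
    """Two-sided Wilcoxon signed-rank test on paired data.

    Zero differences are dropped (Wilcoxon convention).  Exact p-values
    come from full sign enumeration for up to 12 nonzero differences
    (mid-ranks handle tied magnitudes); larger samples use the
    tie-corrected normal approximation.  All-zero differences return
    p = 1 flagged ``all_zero``.
    """
    x = np.asarray(x, dtype=float)
    d = x if y is None else x - np.asarray(y, dtype=float)
    d = d[~np.isnan(d)]
    d = d[d != 0]
    m = len(d)
    if m == 0:
        return RankTestResult(0.0, 1.0, ("all_zero",))
    if m < 2:
        raise ValueError("need at least 2 nonzero differences")
    ranks = sps.rankdata(np.abs(d))
    w_obs = float(ranks[d > 0].sum())

    use_exact = method == "exact" or (method == "auto" and m <= 12)
    if use_exact:
        ws = []
        for signs in itertools.product((0, 1), repeat=m):
            mask = np.array(signs, dtype=bool)
            ws.append(float(ranks[mask].sum()))
        ws = np.array(ws)
        lo = float((ws <= w_obs + 1e-12).mean())
        hi = float((ws >= w_obs - 1e-12).mean())
        return RankTestResult(w_obs, min(1.0, 2.0 * min(lo, hi)))

    mean_w = m * (m + 1) / 4.0
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    var_w = m * (m + 1) * (2 * m + 1) / 24.0 - (
        (tie_counts**3 - tie_counts).sum() / 48.0
    )
    if var_w == 0:
        return RankTestResult(w_obs, 1.0, ("zero_variance",))
    z = (w_obs - mean_w) / math.sqrt(var_w)
    p = 2.0 * float(sps.norm.sf(abs(z)))
    return RankTestResult(w_obs, min(1.0, p))


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: ``min(1, p * m)`` elementwise.

    ``m`` defaults to the family size (the length of ``p_values``).
    """
    p = np.asarray(p_values, dtype=float)
    if m is None:
        m = len(p)
    if m < 1:
        raise ValueError("family size m must be >= 1")
    return np.minimum(1.0, p * m)
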