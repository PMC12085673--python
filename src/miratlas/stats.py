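"""Shared statistical primitives: Spearman rank tests, Welch's t, Cohen's d, BH.

The Spearman p-value follows the classical split used by R's ``cor.test``:
exact enumeration of the distribution of ``S = sum(d_i^2)`` for small
tie-free samples, the AS 89 Edgeworth expansion for larger tie-free samples
(n <= 1289), and the Student-t approximation whenever ties are present or
n is very large.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import permutations
from typing import Literal

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "bh_adjust",
    "spearman_test",
    "welch_t",
    "cohens_d",
    "geometric_mean",
    "geometric_median",
]

# largest n for exact enumeration of the S distribution (8! = 40320 perms)
_EXACT_N = 8
# AS 89 Edgeworth domain bound, as in R's cor.test
_EDGEWORTH_N = 1289


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaN-tolerant)."""
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


@lru_cache(maxsize=16)
def _exact_s_distribution(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact distribution of S = sum((rank_x - rank_y)^2) under the null.

    Returns (support, pmf). Only depends on n; cached.
    """
    base = np.arange(n)
    counts: dict[int, int] = {}
    for perm in permutations(range(n)):
        s = int(np.sum((base - np.array(perm)) ** 2))
        counts[s] = counts.get(s, 0) + 1
    support = np.array(sorted(counts))
    pmf = np.array([counts[s] for s in support], dtype=float)
    pmf /= pmf.sum()
    return support, pmf


def _exact_p(s: float, n: int) -> float:
    support, pmf = _exact_s_distribution(n)
    lower = pmf[support <= s + 0.5].sum()
    upper = pmf[support >= s - 0.5].sum()
    return min(1.0, 2.0 * min(lower, upper))


# AS 89 (Best & Roberts 1975) Edgeworth-series constants, upper tail of S
_C = (0.2274, 0.2531, 0.1745, 0.0758, 0.1033, 0.3932,
      0.0879, 0.0151, 0.0072, 0.0831, 0.0267, 0.004567)


def _as89_upper(s: float, n: int) -> float:
    """P(S >= s) by the AS 89 Edgeworth expansion (tie-free ranks)."""
    c1, c2, c3, c4, c5, c6, c7, c8, c9, c10, c11, c12 = _C
    b = 1.0 / n
    x = (6.0 * (s - 1.0) * b / (n * n - 1.0) - 1.0) * np.sqrt(1.0 / b - 1.0)
    y = x * x
    u = x * b * (c1 + b * (c2 + c3 * b)
                 + y * (-c4 + b * (c5 + c6 * b)
                        - y * b * (c7 + c8 * b
                                   - y * (c9 - c10 * b
                                          + y * b * (c11 - c12 * y)))))
    p = u / np.exp(y / 2.0) + sps.norm.sf(x)
    return float(min(max(p, 0.0), 1.0))


def _t_approx_p(rho: float, n: int) -> float:
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * sps.t.sf(abs(t), n - 2))


def spearman_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman correlation with a two-sided test of rho = 0.

    Returns (rho, p). rho uses midranks; the p-value path depends on ties
    and sample size as described in the module docstring. A constant input
    vector yields (nan, nan).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    ties = (np.unique(x).size < n) or (np.unique(y).size < n)
    if ties or n > _EDGEWORTH_N:
        return rho, _t_approx_p(rho, n)
    s = float(np.sum((rx - ry) ** 2))
    if n <= _EXACT_N:
        return rho, _exact_p(s, n)
    return rho, _edgeworth_two_sided(s, n)


def _edgeworth_two_sided(s: float, n: int) -> float:
    """Two-sided p from AS 89: double the tail S falls in (S-mean split)."""
    if s > (n ** 3 - n) / 6.0:
        p = _as89_upper(s, n)                # P(S >= s), rho below 0
    else:
        p = 1.0 - _as89_upper(s + 2.0, n)    # P(S <= s); S moves in steps of 2
    return min(1.0, 2.0 * p)


def spearman_matrix(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Spearman of each row of X against y, with p-values.

    Vectorized over rows for the correlation; the p-value path is shared
    across rows (same n, tie pattern checked per row).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    rhos = np.full(X.shape[0], np.nan)
    ps = np.full(X.shape[0], np.nan)
    if n < 3 or np.ptp(y) == 0:
        return rhos, ps
    ry = sps.rankdata(y)
    ry_c = ry - ry.mean()
    y_ties = np.unique(y).size < n
    RX = np.apply_along_axis(sps.rankdata, 1, X)
    RXc = RX - RX.mean(axis=1, keepdims=True)
    denom = np.sqrt((RXc ** 2).sum(axis=1) * (ry_c ** 2).sum())
    const = denom == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        rhos = (RXc @ ry_c) / denom
    rhos[const] = np.nan
    for i in range(X.shape[0]):
        if const[i]:
            continue
        row_ties = y_ties or np.unique(X[i]).size < n
        if row_ties or n > _EDGEWORTH_N:
            ps[i] = _t_approx_p(float(rhos[i]), n)
        else:
            s = float(np.sum((RX[i] - ry) ** 2))
            if n <= _EXACT_N:
                ps[i] = _exact_p(s, n)
            else:
                ps[i] = _edgeworth_two_sided(s, n)
    return rhos, ps


def welch_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Welch's t-test statistic and p-value."""
    res = sps.ttest_ind(np.asarray(a, float), np.asarray(b, float),
                        equal_var=False)
    return float(res.statistic), float(res.pvalue)


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Standardized mean difference (mean_a - mean_b) / pooled sd."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
                     / (na + nb - 2))
    if pooled == 0:
        return float("nan")
    return float((a.mean() - b.mean()) / pooled)


def geometric_mean(x: np.ndarray, exclude_zero: bool = True) -> float:
    """Geometric mean; zeros optionally excluded (log-scale mean otherwise -inf)."""
    x = np.asarray(x, dtype=float)
    if exclude_zero:
        x = x[x > 0]
    if x.size == 0:
        return 0.0
    return float(np.exp(np.mean(np.log(x))))


def geometric_median(x: np.ndarray, exclude_zero: bool = True) -> float:
    """Scalar geometric median: exp(median(log x)); zeros optionally excluded."""
    x = np.asarray(x, dtype=float)
    if exclude_zero:
        x = x[x > 0]
    if x.size == 0:
        return 0.0
    return float(np.exp(np.median(np.log(x))))


def group_center(x: np.ndarray, kind: Literal["median", "geometric_mean",
                                              "geometric_median"]) -> float:
    if kind == "median":
        return float(np.median(np.asarray(x, float)))
    if kind == "geometric_mean":
        return geometric_mean(x)
    if kind == "geometric_median":
        return geometric_median(x)
    raise ValueError(f"unknown center statistic: {kind!r}")
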