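"""Shared rank statistics.

Exact Wilcoxon rank-sum p-values are computed by full enumeration of
rank splits (mid-ranks, so ties are handled), which scipy's exact
method does not offer; the asymptotic path delegates to scipy with tie
and continuity corrections.  Spearman correlation uses an exact
permutation p-value for n <= 9 and the t approximation otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations
from math import comb

import numpy as np
from scipy import stats

ALTERNATIVES = ("two_sided", "greater", "less")

_EPS = 1e-9


@dataclass
class AssociationResult:
    statistic_name: str
    estimate: float
    p_value: float
    n: int
    alternative: str = "two_sided"

    def __post_init__(self) -> None:
        if self.alternative not in ALTERNATIVES:
            raise ValueError(f"alternative must be one of {ALTERNATIVES}")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def _scipy_alternative(alternative: str) -> str:
    return {"two_sided": "two-sided", "greater": "greater", "less": "less"}[alternative]


def rank_sum_exact(a, b, alternative: str = "two_sided") -> tuple[float, float]:
    """Exact rank-sum test by full enumeration of all C(n_a+n_b, n_a) rank splits.

    Ties receive mid-ranks.  Returns (W, p) where W is the rank sum of
    group ``a``.  Cost is combinatorial; intended for group sizes <= ~10.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n_a, n_b = len(a), len(b)
    ranks = stats.rankdata(np.concatenate([a, b]))
    w_obs = float(ranks[:n_a].sum())
    idx = np.array(list(combinations(range(n_a + n_b), n_a)))
    sums = ranks[idx].sum(axis=1)
    total = comb(n_a + n_b, n_a)
    p_greater = float(np.count_nonzero(sums >= w_obs - _EPS)) / total
    p_less = float(np.count_nonzero(sums <= w_obs + _EPS)) / total
    if alternative == "greater":
        p = p_greater
    elif alternative == "less":
        p = p_less
    else:
        p = min(1.0, 2.0 * min(p_greater, p_less))
    return w_obs, p


def rank_sum_test(a, b, alternative: str = "two_sided", exact_max_n: int = 10) -> AssociationResult:
    """Wilcoxon rank-sum test; exact enumeration when both groups are small.

    The asymptotic branch uses the normal approximation with tie
    correction and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if len(a) <= exact_max_n and len(b) <= exact_max_n:
        w, p = rank_sum_exact(a, b, alternative)
        return AssociationResult("wilcoxon_W", w, p, len(a) + len(b), alternative)
    res = stats.mannwhitneyu(a, b, alternative=_scipy_alternative(alternative),
                             method="asymptotic", use_continuity=True)
    w = float(res.statistic + len(a) * (len(a) + 1) / 2.0)  # U -> rank sum of a
    return AssociationResult("wilcoxon_W", w, float(res.pvalue), len(a) + len(b), alternative)


def spearman(x, y, alternative: str = "two_sided") -> AssociationResult:
    """Spearman rank correlation; exact permutation p for n <= 9, else t approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined: zero variance in an input")
    rho = float(stats.spearmanr(x, y).statistic)
    if n <= 9:
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        count = 0
        total = 0
        for perm in permutations(range(n)):
            r = np.corrcoef(rx, ry[list(perm)])[0, 1]
            if alternative == "greater":
                count += r >= rho - _EPS
            elif alternative == "less":
                count += r <= rho + _EPS
            else:
                count += abs(r) >= abs(rho) - _EPS
            total += 1
        p = count / total
    else:
        p = float(stats.spearmanr(x, y, alternative=_scipy_alternative(alternative)).pvalue)
    return AssociationResult("spearman_rho", rho, min(1.0, float(p)), n, alternative)


def partial_spearman(
    y,
    x,
    covariates=None,
    alternative: str = "two_sided",
    method: str = "t",
    n_permutations: int = 10000,
    rng: np.random.Generator | None = None,
) -> AssociationResult:
    """Covariate-adjusted Spearman correlation by rank residualization.

    All variables are mid-rank transformed; rank(y) and rank(x) are
    each residualized on the covariate ranks (with intercept) by least
    squares, and the Pearson correlation of the residual series is the
    partial rho.  The p-value uses a t approximation on n - 2 - c
    degrees of freedom, or a free permutation of the x residuals when
    ``method='permutation'``.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = len(y)
    if n < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(y) == 0 or np.ptp(x) == 0:
        raise ValueError("partial Spearman undefined: zero variance in y or x")
    ry = stats.rankdata(y)
    rx = stats.rankdata(x)
    # covariates: accept None, 1-D array, or 2-D array (n x c)
    if covariates is None:
        cov = np.empty((n, 0))
    else:
        arr = np.asarray(covariates, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        if arr.shape[0] != n:
            arr = arr.T
        cov = np.column_stack([stats.rankdata(arr[:, j]) for j in range(arr.shape[1])]) if arr.shape[1] else np.empty((n, 0))
    c = cov.shape[1]
    design = np.column_stack([np.ones(n), cov])
    res_y = ry - design @ np.linalg.lstsq(design, ry, rcond=None)[0]
    res_x = rx - design @ np.linalg.lstsq(design, rx, rcond=None)[0]
    denom = np.sqrt((res_y ** 2).sum() * (res_x ** 2).sum())
    if denom == 0:
        raise ValueError("partial Spearman undefined: residuals have zero variance")
    rho = float((res_y * res_x).sum() / denom)
    rho = max(-1.0, min(1.0, rho))

    if method == "permutation":
        rng = rng if rng is not None else np.random.default_rng()
        perm_rho = np.empty(n_permutations)
        for i in range(n_permutations):
            perm = rng.permutation(res_x)
            perm_rho[i] = (res_y * perm).sum() / denom
        if alternative == "greater":
            p = (1 + np.count_nonzero(perm_rho >= rho - _EPS)) / (n_permutations + 1)
        elif alternative == "less":
            p = (1 + np.count_nonzero(perm_rho <= rho + _EPS)) / (n_permutations + 1)
        else:
            p = (1 + np.count_nonzero(np.abs(perm_rho) >= abs(rho) - _EPS)) / (n_permutations + 1)
    else:
        df = n - 2 - c
        if df <= 0:
            raise ValueError("too few observations for the covariate count")
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt(df / (1.0 - rho ** 2))
            if alternative == "greater":
                p = float(stats.t.sf(t, df))
            elif alternative == "less":
                p = float(stats.t.cdf(t, df))
            else:
                p = float(2.0 * stats.t.sf(abs(t), df))
    return AssociationResult("partial_spearman_rho", rho, min(1.0, float(p)), n, alternative)
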