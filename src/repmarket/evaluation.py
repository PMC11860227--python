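"""Forecast- and replication-evaluation statistics.

Exact binomial (Clopper-Pearson) intervals for replication rates, exact
2x2 tests (Fisher conditional, Boschloo unconditional) for comparing
tier replication rates, correlation measures relating forecasts to
outcomes, probabilistic forecast scores, and the paired signed-rank
test for effect-size shrinkage.
"""

from __future__ import annotations

import math
from typing import NamedTuple, Sequence, Tuple

import numpy as np
from scipy import stats
from scipy.stats import beta, binom, hypergeom, norm, t as t_dist

__all__ = [
    "clopper_pearson",
    "fisher_exact",
    "boschloo",
    "point_biserial",
    "forecast_scores",
    "wilcoxon_signed_rank",
    "kendall_tau_b",
    "pearson_with_test",
    "CorrelationResult",
]


class CorrelationResult(NamedTuple):
    r: float
    t_stat: float
    p: float
    ci: Tuple[float, float]


def clopper_pearson(k: int, n: int, level: float = 0.95) -> Tuple[float, float]:
    """Exact (tail-inversion) binomial confidence interval for k/n.

    Computed from beta quantiles; the lower bound is 0 when k = 0 and
    the upper bound is 1 when k = n.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if not (0 <= k <= n):
        raise ValueError("k must lie in [0, n]")
    a = (1.0 - level) / 2.0
    lower = 0.0 if k == 0 else float(beta.ppf(a, k, n - k + 1))
    upper = 1.0 if k == n else float(beta.ppf(1.0 - a, k + 1, n - k))
    return lower, upper


def _check_table(table) -> np.ndarray:
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        if np.any(t != np.floor(t)) or np.any(t < 0):
            raise ValueError("table entries must be non-negative integers")
        t = t.astype(int)
    return t


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table.

    Two-sidedness follows the probability-mass criterion: the sum of
    hypergeometric probabilities of all tables (with the observed
    margins) no more probable than the observed one.
    """
    t = _check_table(table)
    if t.sum(axis=0).min() == 0 and t.sum(axis=1).min() == 0:
        raise ValueError("degenerate table: empty margins")
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def _fisher_stat_matrix(n1: int, n2: int, alternative: str) -> np.ndarray:
    """Fisher p value of every table with fixed row totals (n1, n2).

    Entry [a, b] is the Fisher p of the table [[a, n1-a], [b, n2-b]]
    under the given alternative; used as the ordering statistic of the
    unconditional test.
    """
    a = np.arange(n1 + 1)[:, None]
    b = np.arange(n2 + 1)[None, :]
    total = a + b  # column-1 margin
    n = n1 + n2
    if alternative == "greater":  # p1 > p2
        return hypergeom.sf(a - 1, n, total, n1)
    if alternative == "less":
        return hypergeom.cdf(a, n, total, n1)
    if alternative == "two-sided":
        out = np.empty((n1 + 1, n2 + 1))
        for j in range(n2 + 1):
            for i in range(n1 + 1):
                m = int(i + j)
                support = np.arange(max(0, m - n2), min(n1, m) + 1)
                pmf = hypergeom.pmf(support, n, m, n1)
                obs = hypergeom.pmf(i, n, m, n1)
                out[i, j] = pmf[pmf <= obs * (1.0 + 1e-10)].sum()
        return np.minimum(out, 1.0)
    raise ValueError(f"unknown alternative {alternative!r}")


def boschloo(table, grid_points: int = 1000, alternative: str = "two-sided") -> float:
    """Boschloo's exact unconditional test for a 2x2 table.

    The design fixes the row totals (group sizes).  The ordering
    statistic is the Fisher p value (one-sided for the one-sided test,
    probability-mass two-sided for the two-sided test); the p value is
    the supremum over the nuisance success probability, on a uniform
    grid of ``grid_points`` points, of the probability under independent
    binomials of a table at least as extreme as the observed one.  The
    test is uniformly more powerful than Fisher's: its p never exceeds
    the corresponding Fisher p.
    """
    t = _check_table(table)
    n1, n2 = int(t[0].sum()), int(t[1].sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("degenerate table: an empty row")
    x1, x2 = int(t[0, 0]), int(t[1, 0])

    stat = _fisher_stat_matrix(n1, n2, alternative)
    mask = stat <= stat[x1, x2] * (1.0 + 1e-10)

    grid = np.linspace(1e-8, 1.0 - 1e-8, grid_points)
    pmf1 = binom.pmf(np.arange(n1 + 1)[:, None], n1, grid[None, :])
    pmf2 = binom.pmf(np.arange(n2 + 1)[:, None], n2, grid[None, :])
    # P_pi(extreme region) for every nuisance value pi on the grid
    rows = np.where(mask.any(axis=1))[0]
    acc = np.zeros_like(grid)
    for i in rows:
        cols = mask[i]
        acc += pmf1[i] * pmf2[cols].sum(axis=0)
    return float(min(acc.max(), 1.0))


def point_biserial(values: Sequence[float], flags: Sequence[bool], level: float = 0.95) -> CorrelationResult:
    """Correlation between a continuous variable and a binary outcome.

    Pearson correlation with the flags coded 0/1, with its t-test on
    n - 2 degrees of freedom and a Fisher-z confidence interval.
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(flags, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.unique(y).size < 2:
        raise ValueError("both outcome classes must be present")
    if np.ptp(x) == 0:
        raise ValueError("values must not be constant")
    return pearson_with_test(x, y, level=level)


def pearson_with_test(x, y, level: float = 0.95) -> CorrelationResult:
    """Pearson r with its t-test and Fisher-z confidence interval."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n != y.size or n < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("inputs must not be constant")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(min(r, 1.0), -1.0)
    if abs(r) == 1.0:
        t_stat, p = math.inf * math.copysign(1, r), 0.0
    else:
        t_stat = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * t_dist.sf(abs(t_stat), n - 2)
    zq = norm.ppf(0.5 * (1.0 + level))
    zr = np.arctanh(r)
    half = zq / math.sqrt(n - 3)
    ci = (float(np.tanh(zr - half)), float(np.tanh(zr + half)))
    return CorrelationResult(r=r, t_stat=float(t_stat), p=float(p), ci=ci)


def forecast_scores(forecasts, outcomes) -> Tuple[float, float]:
    """Mean absolute error and mean Brier (squared) error of forecasts."""
    f = np.asarray(forecasts, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if f.size != y.size or f.size == 0:
        raise ValueError("forecasts and outcomes must have equal nonzero length")
    return float(np.mean(np.abs(f - y))), float(np.mean((f - y) ** 2))


def wilcoxon_signed_rank(x, y) -> Tuple[float, float]:
    """Paired Wilcoxon signed-rank test, normal approximation.

    Zero differences are dropped, ties receive midranks, the variance
    carries the tie correction, and no continuity correction is
    applied.  Returns ``(z, p_two_sided)`` with z positive when x tends
    to exceed y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all paired differences are zero")
    ranks = stats.rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, counts = np.unique(ranks, return_counts=True)
    var -= (counts**3 - counts).sum() / 48.0
    if var <= 0:
        raise ValueError("degenerate rank variance")
    z = (w_plus - mu) / math.sqrt(var)
    return float(z), float(2.0 * norm.sf(abs(z)))


def kendall_tau_b(x, y) -> float:
    """Kendall's tau-b rank correlation (tie-corrected in both margins)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need at least 2 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("a fully tied margin leaves tau-b undefined")
    return float(stats.kendalltau(x, y, variant="b").statistic)
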