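"""Regression form of the geometric series and slope comparison.

A community that follows niche preemption falls on a straight line when
log abundance is plotted against rank: ``log(a_r) = b0 + b1 * r``.  The
slope ``b1`` summarises how steeply dominance decays, so two assemblages
can be compared by testing equality of their slopes with the classical
ANCOVA interaction F-test on the pooled model
``log(a) ~ rank + group + rank:group``.

Base-10 logarithms are the default (intercepts for communities of a few
hundred to a few thousand individuals then sit conveniently in the 2-3
range); natural logs are available via ``base``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .sad import RankAbundance

__all__ = ["RegressionFit", "fit_rad_regression", "compare_slopes"]


@dataclass
class RegressionFit:
    """OLS fit of log abundance on rank."""

    intercept: float
    slope: float
    se_intercept: float
    se_slope: float
    r_squared: float
    f_stat: float
    p_value: float
    df_resid: int
    n: int
    base: float


def _log(a: np.ndarray, base: float) -> np.ndarray:
    return np.log(a) / np.log(base)


def fit_rad_regression(ra: RankAbundance, base: float = 10.0) -> RegressionFit:
    """Ordinary least squares of log(abundance) on rank.

    Requires S >= 3 (one residual degree of freedom) and all abundances
    >= 1.  A zero-variance response (all abundances equal) yields slope 0
    and R-squared reported as 0 with a warning rather than NaN.
    """
    if ra.S < 3:
        raise ValueError("rank-abundance regression requires S >= 3")
    if np.any(ra.abundances < 1):
        raise ValueError("all abundances must be >= 1 for the log transform")
    y = _log(ra.abundances, base)
    X = sm.add_constant(ra.ranks.astype(float))
    res = sm.OLS(y, X).fit()
    if np.allclose(y, y[0]):
        warnings.warn(
            "constant log-abundances: R-squared reported as 0", RuntimeWarning
        )
        r2, f, p = 0.0, 0.0, 1.0
    else:
        r2 = float(res.rsquared)
        f = float(res.fvalue)
        p = float(res.f_pvalue)
    return RegressionFit(
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        se_intercept=float(res.bse[0]),
        se_slope=float(res.bse[1]),
        r_squared=r2,
        f_stat=f,
        p_value=p,
        df_resid=int(res.df_resid),
        n=ra.S,
        base=base,
    )


def compare_slopes(
    ra_a: RankAbundance, ra_b: RankAbundance, base: float = 10.0
) -> tuple[float, float]:
    """Equality-of-slopes F-test between two rank-abundance lines.

    Fits the pooled model ``log(a) ~ rank + group + rank:group`` and
    tests the interaction coefficient; under the null of equal slopes the
    statistic is F with (1, S_A + S_B - 4) degrees of freedom.  Symmetric
    in its arguments.
    """
    for ra in (ra_a, ra_b):
        if ra.S < 3:
            raise ValueError("each assemblage needs S >= 3")
        if np.any(ra.abundances < 1):
            raise ValueError("all abundances must be >= 1")
    y = np.concatenate([_log(ra_a.abundances, base), _log(ra_b.abundances, base)])
    rank = np.concatenate([ra_a.ranks, ra_b.ranks]).astype(float)
    group = np.concatenate([np.zeros(ra_a.S), np.ones(ra_b.S)])
    X_full = sm.add_constant(np.column_stack([rank, group, rank * group]))
    X_red = sm.add_constant(np.column_stack([rank, group]))
    df_resid = ra_a.S + ra_b.S - 4
    if df_resid < 1 or np.linalg.matrix_rank(X_full) < 4:
        raise ValueError("degenerate pooled design for slope comparison")
    rss_full = float(sm.OLS(y, X_full).fit().ssr)
    rss_red = float(sm.OLS(y, X_red).fit().ssr)
    if rss_full <= 0:
        # both lines exact: identical slopes -> F = 0, else infinite evidence
        if np.isclose(rss_red, 0.0):
            return 0.0, 1.0
        return float("inf"), 0.0
    f = (rss_red - rss_full) / (rss_full / df_resid)
    f = max(f, 0.0)
    p = float(stats.f.sf(f, 1, df_resid))
    return float(f), p
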