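"""Between-site beta-diversity: Morisita dissimilarity, paired t, Mantel.

The classical Morisita overlap of two count vectors x, y is

    C = 2 * sum(x_i * y_i) / ((lam_x + lam_y) * X * Y),

with ``lam_x = sum x_i (x_i - 1) / (X (X - 1))`` (Simpson's concentration
with the small-sample correction) and ``X = sum x_i``.  Beta-diversity is
``1 - C``.  Because of the finite-count correction C can slightly exceed
1, so the dissimilarity can dip below 0; values are reported unclamped
(with a warning) since averages over site pairs depend on them.

The Morisita-Horn variant (relative-abundance based, bounded in [0, 1])
is offered as an option but is not the default: the intended inputs are
raw integer counts.

Between-year inference: a paired Student t-test on the vectorised upper
triangles (site pairs matched across years), and a Mantel test (Pearson
correlation of upper triangles, one-tailed for positive association by
default) with simultaneous row/column permutations of one matrix.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .community import AbundanceTable, pool

__all__ = [
    "DistanceMatrix",
    "morisita_dissimilarity",
    "morisita_horn_dissimilarity",
    "beta_matrix",
    "paired_beta_test",
    "mantel",
]


def _lam(x: np.ndarray) -> float:
    X = x.sum()
    return float((x * (x - 1)).sum() / (X * (X - 1)))


def morisita_dissimilarity(x, y) -> float:
    """Classical (count-based) Morisita dissimilarity 1 - C.

    ``x`` and ``y`` must be aligned on the same species order; each must
    total at least 2 individuals (the correction is undefined below).
    Identical vectors give 0 (to rounding); disjoint support gives
    exactly 1; the value is not clamped and may be slightly negative.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("count vectors must be aligned on the same species")
    X, Y = x.sum(), y.sum()
    if X < 2 or Y < 2:
        raise ValueError("each community needs at least 2 individuals")
    c = 2.0 * float((x * y).sum()) / ((_lam(x) + _lam(y)) * X * Y)
    d = 1.0 - c
    if d < 0:
        warnings.warn(
            f"Morisita dissimilarity {d:.4g} < 0 (overlap exceeds 1); "
            "reported unclamped",
            RuntimeWarning,
        )
    return d


def morisita_horn_dissimilarity(x, y) -> float:
    """Morisita-Horn dissimilarity (relative abundances, no correction)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("count vectors must be aligned on the same species")
    px, py = x / x.sum(), y / y.sum()
    c = 2.0 * float((px * py).sum()) / float((px * px).sum() + (py * py).sum())
    return 1.0 - c


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarities among sites for one stratum-year."""

    sites: list
    values: np.ndarray
    year: object = None
    stratum: str = "all"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if v.shape[0] != len(self.sites):
            raise ValueError("site labels do not match matrix size")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("diagonal must be zero")
        if not np.all(np.isfinite(v)):
            raise ValueError("entries must be finite")
        self.values = v

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def condensed(self) -> np.ndarray:
        """Upper triangle, row-major — pair order (0,1), (0,2), ..."""
        iu = np.triu_indices(self.n_sites, k=1)
        return self.values[iu]

    def pair_labels(self) -> list[tuple]:
        return list(itertools.combinations(self.sites, 2))


def beta_matrix(
    table: AbundanceTable,
    year,
    stratum: str = "all",
    metric: str = "morisita",
) -> DistanceMatrix:
    """All pairwise site dissimilarities within one year and stratum.

    Sites are pooled over their replicate samples; species absent from a
    site pair's union contribute zero and do not affect the index.
    """
    sites = table.sites()
    if len(sites) < 2:
        raise ValueError("need at least 2 sites")
    fn = {
        "morisita": morisita_dissimilarity,
        "morisita_horn": morisita_horn_dissimilarity,
    }[metric]
    master = table.species_ids
    vecs = {}
    for site in sites:
        c = pool(table, stratum, year=year, site=site)
        vecs[site] = c.as_series().reindex(master, fill_value=0).to_numpy()
    m = np.zeros((len(sites), len(sites)))
    for i, j in itertools.combinations(range(len(sites)), 2):
        m[i, j] = m[j, i] = fn(vecs[sites[i]], vecs[sites[j]])
    return DistanceMatrix(sites=sites, values=m, year=year, stratum=stratum)


def _check_aligned(ma: DistanceMatrix, mb: DistanceMatrix) -> None:
    if ma.sites != mb.sites:
        raise ValueError("matrices must share the same site set and order")


def paired_beta_test(ma: DistanceMatrix, mb: DistanceMatrix) -> tuple[float, float]:
    """Paired Student t-test on matched site-pair dissimilarities.

    Pairs are the upper-triangle entries matched across years; the test
    is two-sided with n_pairs - 1 degrees of freedom.  Identical matrices
    give (0, 1); zero variance of the differences with a nonzero mean is
    an error (the t statistic is unbounded).  Note the site pairs of a
    distance matrix are not mutually independent; no correction for this
    is applied.
    """
    _check_aligned(ma, mb)
    da, db = ma.condensed(), mb.condensed()
    diff = da - db
    if np.allclose(diff, 0.0):
        return 0.0, 1.0
    if np.isclose(diff.std(ddof=1), 0.0):
        raise ValueError("zero variance of pair differences with nonzero mean")
    t, p = stats.ttest_rel(da, db)
    return float(t), float(p)


def _upper(m: np.ndarray) -> np.ndarray:
    return m[np.triu_indices(m.shape[0], k=1)]


def mantel(
    ma: DistanceMatrix,
    mb: DistanceMatrix,
    reps: int = 10000,
    seed: int = 0,
    alternative: str = "greater",
    exact: bool | None = None,
) -> tuple[float, float]:
    """Mantel test: Pearson correlation of two distance matrices.

    One matrix's rows and columns are permuted simultaneously; the
    p-value counts permuted correlations at least as extreme as the
    observed one, add-one corrected.  ``alternative="greater"`` (the
    default) tests for positive association; ``"two-sided"`` is also
    available.  With ``exact=True`` all n! site relabelings are
    enumerated and the p-value is the exact fraction, identity included
    (feasible for small site sets only).
    """
    _check_aligned(ma, mb)
    n = ma.n_sites
    if n < 3:
        raise ValueError("Mantel test needs at least 3 sites")
    xa = _upper(ma.values)
    r_obs = float(np.corrcoef(xa, _upper(mb.values))[0, 1])

    def stat(perm: np.ndarray) -> float:
        pm = mb.values[np.ix_(perm, perm)]
        return float(np.corrcoef(xa, _upper(pm))[0, 1])

    if exact is None:
        exact = False
    elif exact and math.factorial(n) > 50000:
        raise ValueError("exact enumeration infeasible for this many sites")
    tol = 1e-12
    if exact:
        rs = np.array([stat(np.array(p)) for p in itertools.permutations(range(n))])
        if alternative == "greater":
            p = float(np.mean(rs >= r_obs - tol))
        else:
            p = float(np.mean(np.abs(rs) >= abs(r_obs) - tol))
        return r_obs, p
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(reps):
        perm = rng.permutation(n)
        r = stat(perm)
        if alternative == "greater":
            count += r >= r_obs - tol
        else:
            count += abs(r) >= abs(r_obs) - tol
    return r_obs, (count + 1) / (reps + 1)
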