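"""Diversity, dominance and evenness indices with resampling inference.

Seven classical community descriptors are provided, all on natural
logarithms where a log appears:

* Shannon entropy          ``H' = -sum p_i ln p_i``
* Simpson dominance        ``D  = sum p_i**2``
* Buzas-Gibson evenness    ``E  = e**H' / S``
* Margalef richness        ``Mg = (S - 1) / ln n``
* Menhinick richness       ``Me = S / sqrt(n)``
* Pielou evenness          ``J' = H' / ln S``
* Berger-Parker dominance  ``d  = n_max / n``

Confidence intervals are percentile bootstrap over multinomial resamples
of the ``n`` observed individuals.  Between-community comparisons use a
fixed-margin permutation test: random species x 2 contingency tables with
the observed row totals (pooled species counts) and column totals (the
two community sizes) are drawn with Patefield's algorithm — i.e. from the
margin-conditioned multiple-hypergeometric law, each table weighted by
the number of individual-level arrangements realising it, exactly the
null of randomly re-assigning pooled individuals to the two samples.
The p-value is the fraction of replicate index differences at least as
large in absolute value as the observed one (add-one on both numerator
and denominator, so p > 0 always).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .community import CommunityVector

__all__ = [
    "INDEX_NAMES",
    "shannon",
    "simpson_dominance",
    "buzas_gibson",
    "margalef",
    "menhinick",
    "pielou",
    "berger_parker",
    "pielou_from_entropy",
    "buzas_gibson_from_entropy",
    "compute_index",
    "bootstrap_ci",
    "diversity_profile",
    "permutation_compare",
    "DiversityProfile",
    "PermutationResult",
]


# ---------------------------------------------------------------------------
# vectorised kernels: rows = replicate communities, columns = species slots
# ---------------------------------------------------------------------------

def _shannon_m(a: np.ndarray) -> np.ndarray:
    n = a.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = a / n
        t = np.where(a > 0, p * np.log(p), 0.0)
    return -t.sum(axis=1)


def _simpson_m(a: np.ndarray) -> np.ndarray:
    n = a.sum(axis=1, keepdims=True)
    p = a / n
    return (p * p).sum(axis=1)


def _richness_m(a: np.ndarray) -> np.ndarray:
    return (a > 0).sum(axis=1)


def _buzas_gibson_m(a: np.ndarray) -> np.ndarray:
    return np.exp(_shannon_m(a)) / _richness_m(a)


def _margalef_m(a: np.ndarray) -> np.ndarray:
    return (_richness_m(a) - 1) / np.log(a.sum(axis=1))


def _menhinick_m(a: np.ndarray) -> np.ndarray:
    return _richness_m(a) / np.sqrt(a.sum(axis=1))


def _pielou_m(a: np.ndarray) -> np.ndarray:
    # S = 1 replicates get evenness 0 by convention (resampling continuity);
    # the scalar entry point rejects S = 1 outright.
    s = _richness_m(a)
    h = _shannon_m(a)
    out = np.zeros(a.shape[0])
    ok = s > 1
    out[ok] = h[ok] / np.log(s[ok])
    return out


def _berger_parker_m(a: np.ndarray) -> np.ndarray:
    return a.max(axis=1) / a.sum(axis=1)


_KERNELS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "shannon": _shannon_m,
    "simpson": _simpson_m,
    "buzas_gibson": _buzas_gibson_m,
    "margalef": _margalef_m,
    "menhinick": _menhinick_m,
    "pielou": _pielou_m,
    "berger_parker": _berger_parker_m,
}

INDEX_NAMES = tuple(_KERNELS)


def _kernel(index: str) -> Callable[[np.ndarray], np.ndarray]:
    try:
        return _KERNELS[index]
    except KeyError:
        raise ValueError(
            f"unknown index {index!r}; choose from {INDEX_NAMES}"
        ) from None


# ---------------------------------------------------------------------------
# scalar entry points
# ---------------------------------------------------------------------------

def shannon(c: CommunityVector) -> float:
    """Shannon entropy in nats; 0 for a single-species community."""
    return float(_shannon_m(c.abundances[None, :])[0])


def simpson_dominance(c: CommunityVector) -> float:
    """Simpson dominance, the probability two random individuals conspecific."""
    return float(_simpson_m(c.abundances[None, :])[0])


def buzas_gibson(c: CommunityVector) -> float:
    """Buzas-Gibson evenness e**H'/S, 1 iff all species equally abundant."""
    return float(np.exp(shannon(c)) / c.S)


def margalef(c: CommunityVector) -> float:
    """Margalef richness (S - 1)/ln n; requires n >= 2."""
    if c.n < 2:
        raise ValueError("Margalef index requires n >= 2")
    return float((c.S - 1) / np.log(c.n))


def menhinick(c: CommunityVector) -> float:
    """Menhinick richness S/sqrt(n)."""
    return float(c.S / np.sqrt(c.n))


def pielou(c: CommunityVector) -> float:
    """Pielou evenness H'/ln S; undefined (error) for S = 1."""
    if c.S < 2:
        raise ValueError("Pielou evenness undefined for S = 1")
    return float(shannon(c) / np.log(c.S))


def berger_parker(c: CommunityVector) -> float:
    """Berger-Parker dominance n_max/n."""
    return float(c.n_max / c.n)


def pielou_from_entropy(h: float, s: int) -> float:
    """Pielou evenness from an already-known entropy and richness."""
    if s < 2:
        raise ValueError("Pielou evenness undefined for S = 1")
    return float(h / np.log(s))


def buzas_gibson_from_entropy(h: float, s: int) -> float:
    """Buzas-Gibson evenness e**H'/S from known entropy and richness."""
    return float(np.exp(h) / s)


def compute_index(c: CommunityVector, index: str) -> float:
    """Evaluate one named index on a community (scalar dispatch)."""
    scalar = {
        "shannon": shannon,
        "simpson": simpson_dominance,
        "buzas_gibson": buzas_gibson,
        "margalef": margalef,
        "menhinick": menhinick,
        "pielou": pielou,
        "berger_parker": berger_parker,
    }
    _kernel(index)  # validate name
    return scalar[index](c)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

@dataclass
class DiversityProfile:
    """Point estimates and bootstrap CIs for all seven indices."""

    estimates: dict[str, float]
    ci_lower: dict[str, float]
    ci_upper: dict[str, float]
    reps: int
    level: float
    seed: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": self.estimates,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
            }
        )


def _resample_matrix(c: CommunityVector, reps: int, rng: np.random.Generator) -> np.ndarray:
    return rng.multinomial(c.n, c.proportions, size=reps)


def bootstrap_ci(
    c: CommunityVector,
    index: str,
    reps: int = 9999,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI for one index.

    Each replicate redraws the ``n`` observed individuals multinomially
    from the observed relative abundances and recomputes the index.  For
    pure-richness indices (Margalef, Menhinick) the interval is degenerate
    whenever every resample retains all S species, which is the typical
    outcome for communities without singleton species.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    kern = _kernel(index)
    rng = np.random.default_rng(seed)
    mat = _resample_matrix(c, reps, rng)
    vals = kern(mat)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(vals, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def diversity_profile(
    c: CommunityVector,
    reps: int = 9999,
    level: float = 0.95,
    seed: int = 0,
) -> DiversityProfile:
    """All seven indices with a shared bootstrap resample stream."""
    rng = np.random.default_rng(seed)
    mat = _resample_matrix(c, reps, rng)
    alpha = (1.0 - level) / 2.0
    est, lo, hi = {}, {}, {}
    for name in INDEX_NAMES:
        if name == "pielou" and c.S < 2:
            continue
        est[name] = compute_index(c, name)
        vals = _kernel(name)(mat)
        q = np.quantile(vals, [alpha, 1.0 - alpha])
        lo[name], hi[name] = float(q[0]), float(q[1])
    return DiversityProfile(est, lo, hi, reps=reps, level=level, seed=seed)


# ---------------------------------------------------------------------------
# fixed-margin permutation comparison
# ---------------------------------------------------------------------------

@dataclass
class PermutationResult:
    """Outcome of a two-community fixed-margin permutation test."""

    index: str
    value_a: float
    value_b: float
    observed_diff: float
    p: float
    reps: int
    seed: int


def _align_union(a: CommunityVector, b: CommunityVector) -> tuple[np.ndarray, np.ndarray]:
    sa = a.as_series()
    sb = b.as_series()
    union = sorted(set(sa.index) | set(sb.index))
    return (
        sa.reindex(union, fill_value=0).to_numpy(),
        sb.reindex(union, fill_value=0).to_numpy(),
    )


def permutation_compare(
    a: CommunityVector,
    b: CommunityVector,
    index: str,
    reps: int = 9999,
    seed: int = 0,
) -> PermutationResult:
    """Test equality of one index between two communities.

    Null model: the two communities are random partitions of the pooled
    individuals.  Replicates are random S x 2 contingency tables with the
    pooled per-species row totals and the (n_a, n_b) column totals, drawn
    by Patefield's algorithm (each table weighted by its multiplicity);
    the two-sided p-value counts replicates whose absolute index
    difference reaches the observed one.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    kern = _kernel(index)
    xa, xb = _align_union(a, b)
    obs_a = float(kern(xa[None, :])[0])
    obs_b = float(kern(xb[None, :])[0])
    obs = abs(obs_a - obs_b)
    # canonical column order so the test is exactly symmetric in (a, b)
    ya, yb = xa, xb
    if (yb.sum(), yb.tolist()) > (ya.sum(), ya.tolist()):
        ya, yb = yb, ya
    row = ya + yb
    col = np.array([ya.sum(), yb.sum()])
    rng = np.random.default_rng(seed)
    tables = stats.random_table(row, col).rvs(
        size=reps, random_state=rng, method="patefield"
    )
    # tables: (reps, S, 2)
    va = kern(tables[:, :, 0])
    vb = kern(tables[:, :, 1])
    diffs = np.abs(va - vb)
    exceed = int(np.count_nonzero(diffs >= obs - 1e-12))
    p = (exceed + 1) / (reps + 1)
    return PermutationResult(
        index=index,
        value_a=obs_a,
        value_b=obs_b,
        observed_diff=obs,
        p=float(p),
        reps=reps,
        seed=seed,
    )
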