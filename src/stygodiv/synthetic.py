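"""Synthetic guild-structured spring-community generator.

Emulates a three-year survey of a spring complex: a master list of 22
copepod species (9 obligate groundwater "stygobites", 13 surface or
generalist "non-stygobites") sampled at 8 spring sites with 4 temporal
replicates of 3 subsamples each (96 samples per year).

Each preset year fixes, per guild, the observed richness, the total
number of individuals and a geometric-series (niche preemption) shape,
so the pooled community reproduces the year's marginal structure
exactly: total individuals, species richness, and the dominant species'
share.  Presets:

======  ==========================  ==========================  =====
year    stygobites (S, J, alpha)    non-stygobites (S, J, alpha)  total
======  ==========================  ==========================  =====
"1997"  9, 582, 0.574               12, 410, 0.304               992
"2005"  8, 961, 0.621               13, 1789, 0.393              2750
"2012"  7, 188, 0.462               11, 722, 0.311               910
======  ==========================  ==========================  =====

Master-list species missing from a year (the 22 -> 21/18 pattern) are
the lowest-expected-abundance members of their guild, mimicking
rare-species turnover.  Between-site heterogeneity is governed by a
Dirichlet concentration ``theta``: each species' total is split across
sites with Dirichlet(theta, ..., theta) weights, then multinomially
across the 12 replicate samples within each site.  Large ``theta``
makes sites compositionally identical (all inter-site Morisita
dissimilarities tend to 0); small ``theta`` concentrates each species
in few sites.  Pooled per-species totals are exact by construction, so
the per-year marginals are deterministic while the site-level structure
is stochastic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .community import AbundanceTable, CommunityVector
from .sad import (
    expected_broken_stick,
    expected_geometric,
    expected_lognormal,
    normal_order_scores,
)

__all__ = [
    "GuildSpec",
    "ScenarioSpec",
    "PRESETS",
    "DEFAULT_THETA",
    "sad_proportions",
    "generate_community",
    "generate_scenario",
    "null_pair",
]

# Default site-heterogeneity concentration; chosen so that the presets'
# mean inter-site Morisita dissimilarity lands in the 0.3-0.65 band
# typical of spring complexes fed by one aquifer.
DEFAULT_THETA = 0.5


@dataclass(frozen=True)
class GuildSpec:
    """SAD shape and size for one guild within a scenario year."""

    guild: str
    n_species: int  # species present this year
    j: int  # individuals this year
    n_species_master: int | None = None  # master-list size (>= n_species)
    model: str = "geometric"
    params: dict = field(default_factory=dict)

    def master_size(self) -> int:
        return self.n_species_master or self.n_species


@dataclass(frozen=True)
class ScenarioSpec:
    """Full specification of one synthetic survey year."""

    name: str
    guilds: tuple[GuildSpec, ...]
    n_sites: int = 8
    n_dates: int = 4
    n_subsamples: int = 3
    theta: float = DEFAULT_THETA
    year: int | None = None

    def __post_init__(self) -> None:
        if self.theta <= 0:
            raise ValueError("theta must be > 0")
        for g in self.guilds:
            if g.j < g.n_species:
                raise ValueError(
                    f"guild {g.guild}: J={g.j} < S={g.n_species} is infeasible"
                )

    @property
    def samples_per_site(self) -> int:
        return self.n_dates * self.n_subsamples

    @property
    def total_j(self) -> int:
        return sum(g.j for g in self.guilds)


PRESETS: dict[str, ScenarioSpec] = {
    "1997": ScenarioSpec(
        name="1997",
        year=1997,
        guilds=(
            GuildSpec("stygobite", 9, 582, 9, params={"alpha": 0.574}),
            GuildSpec("non_stygobite", 12, 410, 13, params={"alpha": 0.304}),
        ),
    ),
    "2005": ScenarioSpec(
        name="2005",
        year=2005,
        guilds=(
            GuildSpec("stygobite", 8, 961, 9, params={"alpha": 0.621}),
            GuildSpec("non_stygobite", 13, 1789, 13, params={"alpha": 0.393}),
        ),
    ),
    "2012": ScenarioSpec(
        name="2012",
        year=2012,
        guilds=(
            GuildSpec("stygobite", 7, 188, 9, params={"alpha": 0.462}),
            GuildSpec("non_stygobite", 11, 722, 13, params={"alpha": 0.311}),
        ),
    ),
}


def sad_proportions(model: str, s: int, params: dict) -> np.ndarray:
    """Expected relative abundances (rank order) of a SAD truncated at S."""
    if model == "geometric":
        raw = expected_geometric(1.0, s, params["alpha"])
    elif model == "broken_stick":
        raw = expected_broken_stick(1.0, s)
    elif model == "lognormal":
        raw = expected_lognormal(
            params.get("mu", 0.0), params["sigma"], normal_order_scores(s)
        )
    else:
        raise ValueError(f"unknown SAD model {model!r}")
    return raw / raw.sum()


def _largest_remainder(expected: np.ndarray, total: int) -> np.ndarray:
    """Round expected counts to integers summing to ``total``, each >= 1."""
    s = expected.size
    if total < s:
        raise ValueError(f"cannot place {total} individuals in {s} species")
    base = np.floor(expected).astype(np.int64)
    short = total - base.sum()
    if short > 0:
        frac = expected - base
        order = np.lexsort((np.arange(s), -frac))  # stable: rank breaks ties
        base[order[:short]] += 1
    elif short < 0:
        order = np.argsort(expected)  # trim the smallest expectations first
        i = 0
        while short < 0:
            j = order[i % s]
            if base[j] > 0:
                base[j] -= 1
                short += 1
            i += 1
    # min-1 enforcement: move singletons from the top of the curve
    while (base == 0).any():
        zero = int(np.argmax(base == 0))
        donor = int(np.argmax(base))
        if base[donor] <= 1:
            raise ValueError("cannot enforce one individual per species")
        base[donor] -= 1
        base[zero] += 1
    return base


def generate_community(
    s: int,
    j: int,
    model: str = "geometric",
    params: dict | None = None,
    seed: int | None = None,
    mode: str = "multinomial",
    prefix: str = "sp",
) -> CommunityVector:
    """Draw (or compute) a single pooled community from a SAD.

    ``mode="expectation"`` rounds the expected abundances to integers by
    the largest-remainder rule (sum exactly ``j``, every species >= 1,
    fully deterministic).  ``mode="multinomial"`` draws ``j`` individuals
    from the expected proportions; species drawn zero times are dropped.
    """
    params = params or {}
    p = sad_proportions(model, s, params)
    ids = np.array([f"{prefix}{i + 1:02d}" for i in range(s)], dtype=object)
    if mode == "expectation":
        counts = _largest_remainder(j * p, j)
    elif mode == "multinomial":
        rng = np.random.default_rng(seed)
        counts = rng.multinomial(j, p)
    else:
        raise ValueError("mode must be 'expectation' or 'multinomial'")
    keep = counts > 0
    return CommunityVector(ids[keep], counts[keep])


def _guild_ids(guild: str, n: int) -> list[str]:
    prefix = {"stygobite": "Styg", "non_stygobite": "Nsty"}[guild]
    return [f"{prefix}{i + 1:02d}" for i in range(n)]


def generate_scenario(
    spec: ScenarioSpec | str,
    seed: int | None = None,
    theta: float | None = None,
) -> AbundanceTable:
    """Generate one survey year as a full species x sample table.

    Accepts a preset name ("1997", "2005", "2012") or a
    :class:`ScenarioSpec`.  Pooled per-species totals are deterministic
    (expectation-mode SAD rounding); only their allocation across sites
    and replicate samples is random.  The returned table carries the
    complete master species list, including species absent this year.
    """
    if isinstance(spec, str):
        try:
            spec = PRESETS[spec]
        except KeyError:
            raise ValueError(
                f"unknown preset {spec!r}; choose from {sorted(PRESETS)}"
            ) from None
    if theta is not None:
        spec = replace(spec, theta=theta)
    rng = np.random.default_rng(seed)

    species: list[str] = []
    guild_of: dict[str, str] = {}
    totals: dict[str, int] = {}
    for g in spec.guilds:
        ids = _guild_ids(g.guild, g.master_size())
        p = sad_proportions(g.model, g.n_species, g.params)
        counts = _largest_remainder(g.j * p, g.j)
        for i, sp in enumerate(ids):
            species.append(sp)
            guild_of[sp] = g.guild
            # absent species are the lowest-expected ranks of the guild
            totals[sp] = int(counts[i]) if i < g.n_species else 0

    sites = [f"site{i + 1}" for i in range(spec.n_sites)]
    sample_ids, meta_rows = [], []
    for site in sites:
        for d in range(spec.n_dates):
            for s in range(spec.n_subsamples):
                sid = f"{spec.name}_{site}_d{d + 1}r{s + 1}"
                sample_ids.append(sid)
                meta_rows.append(
                    {"sample": sid, "site": site, "year": spec.year or 0,
                     "replicate": f"d{d + 1}r{s + 1}"}
                )

    per_site = spec.samples_per_site
    counts = np.zeros((len(species), len(sample_ids)), dtype=np.int64)
    conc = np.full(spec.n_sites, spec.theta)
    for i, sp in enumerate(species):
        n_i = totals[sp]
        if n_i == 0:
            continue
        w = rng.dirichlet(conc)
        by_site = rng.multinomial(n_i, w)
        for k, c_site in enumerate(by_site):
            if c_site == 0:
                continue
            by_sample = rng.multinomial(c_site, np.full(per_site, 1.0 / per_site))
            counts[i, k * per_site:(k + 1) * per_site] += by_sample

    frame = pd.DataFrame(counts, index=species, columns=sample_ids)
    guild = pd.Series({sp: guild_of[sp] for sp in species})
    meta = pd.DataFrame(meta_rows).set_index("sample")
    return AbundanceTable(counts=frame, guild=guild, sample_meta=meta)


def null_pair(
    c: CommunityVector,
    j_a: int,
    j_b: int,
    seed: int | None = None,
) -> tuple[CommunityVector, CommunityVector]:
    """Two independent multinomial draws from one community's proportions.

    The canonical null input for calibrating the fixed-margin
    permutation comparison: both draws share the parent's relative
    abundances, so any index difference is pure sampling noise.
    """
    rng = np.random.default_rng(seed)
    p = c.proportions
    out = []
    for j in (j_a, j_b):
        counts = rng.multinomial(j, p)
        keep = counts > 0
        if not keep.any():
            raise ValueError("draw produced an empty community")
        out.append(CommunityVector(c.species_ids[keep], counts[keep]))
    return out[0], out[1]
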