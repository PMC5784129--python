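"""Species-by-sample abundance tables and pooled community vectors.

This module owns the coordinate conventions used by every downstream
analysis stage: a wide species x sample count matrix with a per-species
ecological guild ("stygobite" / "non_stygobite") and per-sample grouping
metadata (site, year, replicate).  Communities handed to the index, SAD
and beta-diversity machinery are pooled :class:`CommunityVector` objects
in which zero-count species have been dropped, so the species richness
``S`` of a stratum-year reflects only the species actually observed there.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GUILDS",
    "AbundanceTable",
    "CommunityVector",
    "read_abundance_table",
    "write_abundance_table",
    "pool",
]

GUILDS = ("stygobite", "non_stygobite")


def _normalise_guild(label: str) -> str:
    g = str(label).strip().lower().replace("-", "_").replace(" ", "_")
    if g not in GUILDS:
        raise ValueError(
            f"unknown guild label {label!r}; expected one of {GUILDS}"
        )
    return g


@dataclass
class CommunityVector:
    """Pooled abundances of one stratum-year.

    Species are stored in canonical order: descending abundance, ties
    broken by lexical species id.  All abundances are >= 1; zero-count
    species must be dropped before construction (see :func:`pool`).
    """

    species_ids: np.ndarray
    abundances: np.ndarray

    def __post_init__(self) -> None:
        self.species_ids = np.asarray(self.species_ids, dtype=object)
        self.abundances = np.asarray(self.abundances)
        if self.species_ids.size != self.abundances.size:
            raise ValueError("species_ids and abundances differ in length")
        if self.abundances.size == 0:
            raise ValueError("empty community")
        if not np.issubdtype(self.abundances.dtype, np.integer):
            as_int = self.abundances.astype(np.int64)
            if not np.array_equal(as_int, self.abundances):
                raise ValueError("abundances must be integers")
            self.abundances = as_int
        if (self.abundances < 1).any():
            raise ValueError("all abundances must be >= 1 (drop zero species)")
        if len(set(self.species_ids)) != self.species_ids.size:
            raise ValueError("duplicate species ids")
        # canonical order: abundance descending, species id ascending
        order = np.lexsort((self.species_ids.astype(str), -self.abundances))
        self.species_ids = self.species_ids[order]
        self.abundances = self.abundances[order]

    @property
    def n(self) -> int:
        """Total number of individuals (J)."""
        return int(self.abundances.sum())

    @property
    def S(self) -> int:
        """Species richness."""
        return int(self.abundances.size)

    @property
    def n_max(self) -> int:
        """Abundance of the most abundant species."""
        return int(self.abundances.max())

    @property
    def proportions(self) -> np.ndarray:
        return self.abundances / self.n

    def as_series(self) -> pd.Series:
        return pd.Series(self.abundances, index=self.species_ids)


@dataclass
class AbundanceTable:
    """Species x sample integer count matrix with guild and sample metadata.

    Parameters
    ----------
    counts
        DataFrame, rows indexed by species id, columns by sample id.
    guild
        Series mapping species id -> guild in :data:`GUILDS`.
    sample_meta
        DataFrame indexed by sample id with at least columns
        ``site`` and ``year`` (``replicate`` optional).
    """

    counts: pd.DataFrame
    guild: pd.Series
    sample_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        counts = self.counts
        if counts.index.has_duplicates:
            dups = counts.index[counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate species ids: {dups}")
        if counts.columns.has_duplicates:
            dups = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("counts must be numeric")
        bad = ~np.isfinite(arr.astype(float)) | (arr.astype(float) % 1 != 0) | (arr < 0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                "count must be a non-negative integer: species "
                f"{counts.index[i]!r}, sample {counts.columns[j]!r} has "
                f"value {counts.iat[i, j]!r}"
            )
        self.counts = counts.astype(np.int64)
        self.counts.index.name = "species"
        self.counts.columns.name = None
        guild = self.guild.reindex(counts.index)
        if guild.isna().any():
            missing = guild.index[guild.isna()].tolist()
            raise ValueError(f"species without guild label: {missing}")
        self.guild = guild.map(_normalise_guild)
        if self.sample_meta is not None:
            meta = self.sample_meta
            if meta.index.has_duplicates:
                raise ValueError("duplicate sample ids in metadata")
            missing = [s for s in counts.columns if s not in meta.index]
            if missing:
                raise ValueError(f"samples without metadata: {missing}")
            for col in ("site", "year"):
                if col not in meta.columns:
                    raise ValueError(f"sample metadata lacks column {col!r}")
            self.sample_meta = meta.loc[counts.columns]
            self.sample_meta.index.name = "sample"

    @property
    def species_ids(self) -> list:
        return self.counts.index.tolist()

    @property
    def sample_ids(self) -> list:
        return self.counts.columns.tolist()

    @property
    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def species_in_guild(self, guild: str) -> list:
        g = _normalise_guild(guild)
        return self.guild.index[self.guild == g].tolist()

    def years(self) -> list:
        if self.sample_meta is None:
            return []
        return sorted(self.sample_meta["year"].unique().tolist())

    def sites(self) -> list:
        if self.sample_meta is None:
            return []
        return sorted(self.sample_meta["site"].unique().tolist())


def read_abundance_table(
    counts_path: str | Path,
    metadata_path: str | Path | None = None,
    *,
    delimiter: str | None = None,
) -> AbundanceTable:
    """Read a wide-format abundance table (and optional sample metadata).

    The wide dialect is: column 1 = species id, column 2 = guild, remaining
    columns = per-sample integer counts.  The companion metadata CSV maps
    sample id -> site, year (and optionally replicate).  The delimiter is
    inferred from the extension (``.tsv`` -> tab, otherwise comma) unless
    given explicitly.
    """
    counts_path = Path(counts_path)
    sep = delimiter or ("\t" if counts_path.suffix.lower() == ".tsv" else ",")
    raw = pd.read_csv(counts_path, sep=sep, dtype={0: str, 1: str})
    if raw.shape[1] < 3:
        raise ValueError("wide table needs species, guild and >=1 sample column")
    species_col, guild_col = raw.columns[0], raw.columns[1]
    raw = raw.set_index(species_col)
    guild = raw[guild_col]
    counts = raw.drop(columns=[guild_col])
    meta = None
    if metadata_path is not None:
        metadata_path = Path(metadata_path)
        msep = delimiter or ("\t" if metadata_path.suffix.lower() == ".tsv" else ",")
        meta = pd.read_csv(metadata_path, sep=msep, dtype=str)
        meta = meta.set_index(meta.columns[0])
        if "year" in meta.columns:
            meta["year"] = meta["year"].astype(int)
    return AbundanceTable(counts=counts, guild=guild, sample_meta=meta)


def write_abundance_table(
    table: AbundanceTable,
    counts_path: str | Path,
    metadata_path: str | Path | None = None,
    *,
    delimiter: str | None = None,
) -> None:
    """Write the wide dialect produced by :func:`read_abundance_table`.

    The writer emits the identical dialect so that read -> write -> read
    is the identity on counts and metadata.
    """
    counts_path = Path(counts_path)
    sep = delimiter or ("\t" if counts_path.suffix.lower() == ".tsv" else ",")
    out = table.counts.copy()
    out.insert(0, "guild", table.guild)
    out.to_csv(counts_path, sep=sep)
    if metadata_path is not None and table.sample_meta is not None:
        meta = table.sample_meta
        msep = delimiter or ("\t" if Path(metadata_path).suffix.lower() == ".tsv" else ",")
        meta.to_csv(metadata_path, sep=msep)


def _select_samples(table: AbundanceTable, year=None, site=None) -> list:
    samples = list(table.counts.columns)
    if year is None and site is None:
        return samples
    if table.sample_meta is None:
        raise ValueError("sample metadata required to select by year/site")
    meta = table.sample_meta
    mask = pd.Series(True, index=meta.index)
    if year is not None:
        mask &= meta["year"] == year
    if site is not None:
        mask &= meta["site"].astype(str) == str(site)
    return [s for s in samples if mask.get(s, False)]


def pool(
    table: AbundanceTable,
    stratum: str = "all",
    *,
    year=None,
    site=None,
) -> CommunityVector:
    """Pool samples into a single community for one stratum and group.

    ``stratum`` is ``"all"`` or a guild name; ``year``/``site`` restrict
    the samples via the metadata.  Species whose pooled count is zero are
    dropped, so ``S`` reflects the observed richness of the selection.
    """
    samples = _select_samples(table, year=year, site=site)
    if not samples:
        raise ValueError(f"no samples match year={year!r}, site={site!r}")
    sub = table.counts[samples]
    if stratum != "all":
        species = table.species_in_guild(stratum)
        sub = sub.loc[sub.index.intersection(species)]
    totals = sub.sum(axis=1)
    totals = totals[totals > 0]
    if totals.empty:
        raise ValueError(
            f"empty community: stratum={stratum!r}, year={year!r}, site={site!r}"
        )
    return CommunityVector(totals.index.to_numpy(), totals.to_numpy())
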