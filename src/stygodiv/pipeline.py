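"""Full-survey orchestration: indices, SAD fits, regressions, beta-diversity.

Runs the complete analysis over every stratum (all species, stygobites,
non-stygobites) and every year present in the sample metadata, and
writes four table-shaped CSV outputs plus a JSON run manifest:

* ``diversity.csv``   — per index x stratum: point estimate and bootstrap
  CI per year, and the fixed-margin permutation p for each year pair;
* ``sad_fits.csv``    — per model x stratum x year: parameters, AIC,
  delta-AIC and the selection verdict;
* ``rad_regression.csv`` / ``slope_tests.csv`` — log10 rank-abundance
  regressions and pairwise equality-of-slopes F-tests;
* ``beta.csv``        — per stratum: mean +/- SE Morisita dissimilarity
  per year, and per year pair the paired-t and Mantel results.

Each stage draws its seed from the master seed by a stable BLAKE2 hash
of (master_seed, stage name), so changing one stage's replication count
leaves every other stage's random stream untouched.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .alpha import INDEX_NAMES, diversity_profile, permutation_compare
from .beta import beta_matrix, mantel, paired_beta_test
from .community import AbundanceTable, pool
from .rad import compare_slopes, fit_rad_regression
from .sad import rank_abundances, select_model

__all__ = ["AnalysisConfig", "run_full_analysis", "derive_seed"]

log = logging.getLogger("stygodiv")

STRATA = ("all", "stygobite", "non_stygobite")


def derive_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage sub-seed: BLAKE2b hash of (master seed, stage)."""
    h = hashlib.blake2b(f"{master_seed}:{stage}".encode(), digest_size=4)
    return int.from_bytes(h.digest(), "big") % (2**31)


@dataclass
class AnalysisConfig:
    """Knobs of the full analysis; defaults follow standard practice."""

    strata: tuple[str, ...] = STRATA
    bootstrap_reps: int = 9999
    permutation_reps: int = 9999
    mantel_reps: int = 10000
    ci_level: float = 0.95
    aic_tie_threshold: float = 2.0
    log_base: float = 10.0
    seed: int = 0
    out_dir: str | Path = "stygodiv_out"

    def __post_init__(self) -> None:
        for r in (self.bootstrap_reps, self.permutation_reps, self.mantel_reps):
            if r < 1:
                raise ValueError("replication counts must be >= 1")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must be in (0, 1)")


def _communities(table: AbundanceTable, strata, years):
    out = {}
    for stratum in strata:
        for year in years:
            try:
                out[(stratum, year)] = pool(table, stratum, year=year)
            except ValueError:
                log.warning("empty community: stratum=%s year=%s", stratum, year)
    return out


def _diversity_stage(comms, years, config) -> pd.DataFrame:
    rows = []
    pairs = list(itertools.combinations(years, 2))
    for stratum in config.strata:
        profiles = {
            y: diversity_profile(
                comms[(stratum, y)],
                reps=config.bootstrap_reps,
                level=config.ci_level,
                seed=derive_seed(config.seed, f"bootstrap:{stratum}:{y}"),
            )
            for y in years
            if (stratum, y) in comms
        }
        for index in INDEX_NAMES:
            row: dict = {"stratum": stratum, "index": index}
            for y, prof in profiles.items():
                if index not in prof.estimates:
                    continue
                row[f"{y}_estimate"] = prof.estimates[index]
                row[f"{y}_ci_low"] = prof.ci_lower[index]
                row[f"{y}_ci_high"] = prof.ci_upper[index]
            for ya, yb in pairs:
                if (stratum, ya) not in comms or (stratum, yb) not in comms:
                    continue
                res = permutation_compare(
                    comms[(stratum, ya)],
                    comms[(stratum, yb)],
                    index,
                    reps=config.permutation_reps,
                    seed=derive_seed(
                        config.seed, f"permutation:{stratum}:{ya}:{yb}:{index}"
                    ),
                )
                row[f"p_{ya}_vs_{yb}"] = res.p
            rows.append(row)
    return pd.DataFrame(rows)


def _sad_stage(comms, years, config) -> pd.DataFrame:
    rows = []
    for stratum in config.strata:
        for year in years:
            if (stratum, year) not in comms:
                continue
            ra = rank_abundances(comms[(stratum, year)])
            sel = select_model(ra, tie_threshold=config.aic_tie_threshold)
            for fit in sel.fits:
                rows.append(
                    {
                        "stratum": stratum,
                        "year": year,
                        "model": fit.model,
                        **{f"param_{k}": v for k, v in fit.params.items()},
                        "k": fit.k,
                        "loglik": fit.loglik,
                        "aic": fit.aic,
                        "delta_aic": fit.aic - sel.best.aic,
                        "verdict": sel.verdict,
                    }
                )
    return pd.DataFrame(rows)


def _rad_stage(comms, years, config):
    fit_rows, cmp_rows = [], []
    for stratum in config.strata:
        ras = {
            y: rank_abundances(comms[(stratum, y)])
            for y in years
            if (stratum, y) in comms and comms[(stratum, y)].S >= 3
        }
        for y, ra in ras.items():
            fit = fit_rad_regression(ra, base=config.log_base)
            fit_rows.append(
                {
                    "stratum": stratum,
                    "year": y,
                    "slope": fit.slope,
                    "se_slope": fit.se_slope,
                    "intercept": fit.intercept,
                    "se_intercept": fit.se_intercept,
                    "r_squared": fit.r_squared,
                    "f_stat": fit.f_stat,
                    "p_value": fit.p_value,
                    "df_resid": fit.df_resid,
                }
            )
        for ya, yb in itertools.combinations(sorted(ras), 2):
            f, p = compare_slopes(ras[ya], ras[yb], base=config.log_base)
            cmp_rows.append(
                {"stratum": stratum, "year_a": ya, "year_b": yb, "F": f, "p": p}
            )
    return pd.DataFrame(fit_rows), pd.DataFrame(cmp_rows)


def _beta_stage(table, years, config) -> pd.DataFrame:
    rows = []
    for stratum in config.strata:
        mats = {}
        for y in years:
            try:
                mats[y] = beta_matrix(table, y, stratum)
            except ValueError:
                log.warning("beta matrix skipped: stratum=%s year=%s", stratum, y)
        for y, m in mats.items():
            vals = m.condensed()
            rows.append(
                {
                    "stratum": stratum,
                    "comparison": f"{y}",
                    "mean_beta": float(vals.mean()),
                    "se_beta": float(vals.std(ddof=1) / np.sqrt(vals.size)),
                    "n_pairs": int(vals.size),
                }
            )
        for ya, yb in itertools.combinations(sorted(mats), 2):
            t, tp = paired_beta_test(mats[ya], mats[yb])
            r, rp = mantel(
                mats[ya],
                mats[yb],
                reps=config.mantel_reps,
                seed=derive_seed(config.seed, f"mantel:{stratum}:{ya}:{yb}"),
            )
            rows.append(
                {
                    "stratum": stratum,
                    "comparison": f"{ya}_vs_{yb}",
                    "t": t,
                    "t_p": tp,
                    "mantel_r": r,
                    "mantel_p": rp,
                }
            )
    return pd.DataFrame(rows)


def run_full_analysis(
    table: AbundanceTable, config: AnalysisConfig | None = None
) -> dict[str, pd.DataFrame]:
    """Run every stage on one multi-year table and write the report bundle.

    Returns the output tables keyed by name; the same tables are written
    as CSV under ``config.out_dir`` together with ``manifest.json``.
    """
    config = config or AnalysisConfig()
    years = table.years()
    if not years:
        raise ValueError("sample metadata with a 'year' column is required")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    comms = _communities(table, config.strata, years)
    results: dict[str, pd.DataFrame] = {}
    stages = (
        ("diversity", lambda: _diversity_stage(comms, years, config)),
        ("sad_fits", lambda: _sad_stage(comms, years, config)),
        ("rad", lambda: _rad_stage(comms, years, config)),
        ("beta", lambda: _beta_stage(table, years, config)),
    )
    for name, fn in stages:
        log.info("stage %s ...", name)
        try:
            res = fn()
        except Exception as exc:  # noqa: BLE001 - annotate failing stage
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        if name == "rad":
            results["rad_regression"], results["slope_tests"] = res
        else:
            results[name] = res

    float_fmt = "%.10g"
    for name, frame in results.items():
        frame.to_csv(out_dir / f"{name}.csv", index=False, float_format=float_fmt)
    manifest = {
        "package": "stygodiv",
        "version": __version__,
        "config": {k: (str(v) if isinstance(v, Path) else v)
                   for k, v in asdict(config).items()},
        "years": [int(y) for y in years],
        "n_species": len(table.species_ids),
        "n_samples": len(table.sample_ids),
        "grand_total": table.grand_total,
        "stage_seeds": {
            s: derive_seed(config.seed, s) for s in ("bootstrap", "permutation", "mantel")
        },
        "outputs": sorted(f"{n}.csv" for n in results),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return results
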