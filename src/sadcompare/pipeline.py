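"""End-to-end runner: read community tables, fit and compare all models per
site, write per-site and summary CSVs.

Input format: long CSV with header columns ``site_id, species_id, abundance``
(``dataset_id`` optional, defaulting to the file stem).  Abundances must be
positive integers; decimal abundances are a hard error naming the offending
row.

Outputs (all plain CSV, deterministic given input and seed):

- ``results_per_site.csv``  one row per site x family
- ``summary_best_models.csv``  best-model counts/proportions per dataset + overall
- ``loglik_deviations.csv``  per-site deviation from the mean log-likelihood
- ``exclusions.csv``  excluded sites with machine-readable reason codes
- ``run_metadata.json``  config echo, seed, package version
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .distributions import FAMILY_ORDER
from .fitting import Community, fit_all
from .model_selection import (
    DEFAULT_MIN_RICHNESS,
    compare_site,
    loglik_deviation,
)

__all__ = ["RunConfig", "SummaryTables", "read_communities",
           "run_comparison", "summarize_best_models"]

logger = logging.getLogger(__name__)

_REQUIRED_COLUMNS = ("site_id", "species_id", "abundance")

#: Short aliases accepted on the command line.
FAMILY_ALIASES = {
    "logseries": "logseries", "ls": "logseries",
    "poisson_lognormal": "poisson_lognormal", "pln": "poisson_lognormal",
    "neg_binom": "neg_binom", "negbin": "neg_binom", "nb": "neg_binom",
    "zipf": "zipf",
}


@dataclass
class RunConfig:
    input_paths: tuple
    output_dir: str
    seed: int = 0
    min_richness: int = DEFAULT_MIN_RICHNESS
    families: tuple = FAMILY_ORDER
    log_level: str = "INFO"

    def __post_init__(self):
        if isinstance(self.input_paths, (str, Path)):
            self.input_paths = (str(self.input_paths),)
        else:
            self.input_paths = tuple(str(p) for p in self.input_paths)
        self.output_dir = str(self.output_dir)
        fams = []
        for f in self.families:
            canon = FAMILY_ALIASES.get(f)
            if canon is None:
                raise ValueError(f"unknown model family {f!r}")
            fams.append(canon)
        self.families = tuple(f for f in FAMILY_ORDER if f in fams)
        if not self.families:
            raise ValueError("family list is empty")


@dataclass
class SummaryTables:
    per_site: pd.DataFrame
    best_models: pd.DataFrame
    deviations: pd.DataFrame
    exclusions: pd.DataFrame


def read_communities(path) -> list:
    """Read a long-format community CSV into one Community per site."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    if df.empty:
        logger.warning("%s: no data rows", path)
        return []
    if "dataset_id" not in df.columns:
        df["dataset_id"] = path.stem

    abund = pd.to_numeric(df["abundance"], errors="coerce")
    bad = abund.isna() | (abund != np.floor(abund)) | (abund < 1)
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"{path}: row {i + 2} (site {df['site_id'].iloc[i]!r}, species "
            f"{df['species_id'].iloc[i]!r}) has invalid abundance "
            f"{df['abundance'].iloc[i]!r}; abundances must be positive integers")
    df["abundance"] = abund.astype(np.int64)

    dupes = df.duplicated(subset=["site_id", "species_id"], keep=False)
    if dupes.any():
        i = int(np.flatnonzero(dupes.to_numpy())[0])
        raise ValueError(
            f"{path}: duplicate (site, species) pair "
            f"({df['site_id'].iloc[i]!r}, {df['species_id'].iloc[i]!r})")

    communities = []
    for (dataset_id, site_id), grp in df.groupby(
            ["dataset_id", "site_id"], sort=False):
        communities.append(Community(str(site_id), grp["abundance"].to_numpy(),
                                     dataset_id=str(dataset_id)))
    return communities


def _format_params(params):
    return ";".join(f"{k}={v:.12g}" for k, v in sorted(params.items()))


def run_comparison(config: RunConfig) -> SummaryTables:
    """Fit all families to every site and write per-site + summary tables."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    communities = []
    for path in config.input_paths:
        communities.extend(read_communities(path))

    rows = []
    dev_rows = []
    excl_rows = []
    for comm in communities:
        fits = [f for f in fit_all(comm) if f.family in config.families]
        comp = compare_site(fits, comm.richness, comm.site_id,
                            dataset_id=comm.dataset_id,
                            min_richness=config.min_richness)
        for fam in config.families:
            fit = comp.fits[fam]
            rows.append({
                "dataset_id": comm.dataset_id,
                "site_id": comm.site_id,
                "n_species": comm.richness,
                "family": fam,
                "params": _format_params(fit.params),
                "loglik": fit.loglik,
                "K": fit.K,
                "AICc": comp.aicc[fam],
                "delta_AICc": comp.delta_aicc[fam],
                "weight": comp.weight[fam],
                "best": fam == comp.best_family,
                "converged": fit.converged,
                "at_boundary": fit.at_boundary,
                "excluded": comp.excluded,
                "exclude_reason": comp.exclude_reason,
                "tie": comp.tie,
            })
        if comp.excluded:
            excl_rows.append({"dataset_id": comm.dataset_id,
                              "site_id": comm.site_id,
                              "n_species": comm.richness,
                              "reason": comp.exclude_reason})
        try:
            dev = loglik_deviation(fits)
            for fam in config.families:
                dev_rows.append({"dataset_id": comm.dataset_id,
                                 "site_id": comm.site_id, "family": fam,
                                 "loglik_deviation": dev.deviation[fam]})
        except ValueError:
            excl_rows.append({"dataset_id": comm.dataset_id,
                              "site_id": comm.site_id,
                              "n_species": comm.richness,
                              "reason": "nonfinite_loglik_deviation"})

    per_site = pd.DataFrame(rows)
    deviations = pd.DataFrame(dev_rows,
                              columns=["dataset_id", "site_id", "family",
                                       "loglik_deviation"])
    exclusions = pd.DataFrame(excl_rows,
                              columns=["dataset_id", "site_id", "n_species",
                                       "reason"])
    best_models = summarize_best_models(per_site)

    per_site.to_csv(outdir / "results_per_site.csv", index=False)
    best_models.to_csv(outdir / "summary_best_models.csv", index=False)
    deviations.to_csv(outdir / "loglik_deviations.csv", index=False)
    exclusions.to_csv(outdir / "exclusions.csv", index=False)
    meta = {"config": {**asdict(config)}, "package_version": __version__,
            "n_sites": len(communities)}
    meta["config"]["input_paths"] = list(config.input_paths)
    meta["config"]["families"] = list(config.families)
    (outdir / "run_metadata.json").write_text(
        json.dumps(meta, indent=2, sort_keys=True) + "\n")

    return SummaryTables(per_site, best_models, deviations, exclusions)


def summarize_best_models(per_site: pd.DataFrame) -> pd.DataFrame:
    """Best-model counts and proportions per dataset plus an overall row.

    Excluded sites are omitted from the denominators.
    """
    cols = ["dataset_id", "family", "n_best", "proportion", "n_sites_included"]
    if per_site.empty:
        logger.warning("no sites to summarize")
        return pd.DataFrame(columns=cols)
    inc = per_site[~per_site["excluded"]]
    if inc.empty:
        logger.warning("all sites excluded; empty summary")
        return pd.DataFrame(columns=cols)
    families = [f for f in FAMILY_ORDER if f in set(per_site["family"])]

    def _block(df, label):
        n_sites = df[["dataset_id", "site_id"]].drop_duplicates().shape[0]
        wins = df[df["best"]].groupby("family").size()
        out = []
        for fam in families:
            n = int(wins.get(fam, 0))
            out.append({"dataset_id": label, "family": fam, "n_best": n,
                        "proportion": n / n_sites,
                        "n_sites_included": n_sites})
        return out

    blocks = []
    for dataset_id, grp in inc.groupby("dataset_id", sort=True):
        blocks.extend(_block(grp, dataset_id))
    blocks.extend(_block(inc, "overall"))
    return pd.DataFrame(blocks, columns=cols)
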