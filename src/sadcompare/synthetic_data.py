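"""Synthetic community collections with the gross structure of compiled
species-abundance data: many sites, richness from a handful to a few hundred
species, heavy-tailed integer abundances with many singletons.

Every site is generated from its own sub-seed derived from the master seed
by a counter scheme, so any single site can be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distributions import FAMILY_ORDER, make_distribution
from .fitting import Community, fit_all
from .model_selection import compare_site, loglik_deviation

__all__ = ["SyntheticSpec", "generate_collection", "regenerate_site",
           "recovery_experiment", "DEFAULT_RANGES"]

#: Default parameter ranges: heavy-tailed, singleton-rich communities.
DEFAULT_RANGES = {
    "logseries": {"p": (0.9, 0.999)},
    "poisson_lognormal": {"mu": (0.0, 2.0), "sigma": (0.8, 2.0)},
    "neg_binom": {"k": (0.5, 3.0), "q": (0.02, 0.3)},
    "zipf": {"s": (1.2, 2.5)},
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Contract of the synthetic-data generator."""

    n_sites: int
    families: tuple = FAMILY_ORDER
    param_ranges: dict = field(default_factory=lambda: DEFAULT_RANGES)
    richness_range: tuple = (4, 300)     # log-uniform over [S_min, S_max]
    seed: int = 0
    dataset_id: str = "synthetic"

    def __post_init__(self):
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        fams = (self.families,) if isinstance(self.families, str) else tuple(self.families)
        unknown = set(fams) - set(FAMILY_ORDER)
        if unknown:
            raise ValueError(f"unknown families in spec: {sorted(unknown)}")
        if not fams:
            raise ValueError("spec must name at least one generating family")
        object.__setattr__(self, "families", fams)
        s_min, s_max = self.richness_range
        if not (1 <= s_min <= s_max):
            raise ValueError(f"invalid richness range {self.richness_range}")
        for fam in fams:
            ranges = self.param_ranges.get(fam, DEFAULT_RANGES[fam])
            for name, (lo, hi) in ranges.items():
                if not (lo <= hi):
                    raise ValueError(f"empty range for {fam}.{name}: ({lo}, {hi})")
                probe = {n: (l + h) / 2 for n, (l, h) in ranges.items()}
                make_distribution(fam, **probe)  # raises if outside the domain


def _site_rngs(seed, index):
    """Two independent streams per site: one for the site's configuration
    (family, richness, parameters), one for the abundance draws."""
    cfg = np.random.default_rng(np.random.SeedSequence((seed, index, 0)))
    draw = np.random.default_rng(np.random.SeedSequence((seed, index, 1)))
    return cfg, draw


def _draw_site(spec, index):
    cfg, draw = _site_rngs(spec.seed, index)
    family = spec.families[cfg.integers(len(spec.families))]
    s_min, s_max = spec.richness_range
    S = int(np.round(np.exp(cfg.uniform(np.log(s_min), np.log(s_max)))))
    S = int(np.clip(S, s_min, s_max))
    ranges = spec.param_ranges.get(family, DEFAULT_RANGES[family])
    params = {name: float(cfg.uniform(lo, hi))
              for name, (lo, hi) in sorted(ranges.items())}
    abundances = make_distribution(family, **params).sample(S, draw)
    return family, S, params, abundances


def generate_collection(spec: SyntheticSpec):
    """Generate communities plus a ground-truth table.

    Returns ``(communities, truth)`` where ``truth`` is a DataFrame with one
    row per site: site_id, family, richness, and the generating parameters
    (``param_<name>`` columns; NaN for parameters not in the family).
    """
    communities = []
    rows = []
    for i in range(spec.n_sites):
        family, S, params, abundances = _draw_site(spec, i)
        site_id = f"site_{i:05d}"
        communities.append(Community(site_id, abundances, spec.dataset_id))
        row = {"site_id": site_id, "family": family, "richness": S,
               "seed": spec.seed, "site_index": i}
        row.update({f"param_{k}": v for k, v in params.items()})
        rows.append(row)
    truth = pd.DataFrame(rows)
    return communities, truth


def regenerate_site(spec: SyntheticSpec, index: int) -> Community:
    """Rebuild one site from the master seed and its counter index."""
    family, S, params, abundances = _draw_site(spec, index)
    return Community(f"site_{index:05d}", abundances, spec.dataset_id)


def recovery_experiment(spec: SyntheticSpec) -> pd.DataFrame:
    """Fit-and-select on a synthetic collection, scored against ground truth.

    Returns one row per generating family with parameter bias/RMSE, the
    proportion of sites where the generating family wins on AICc, and the
    generating family's mean Akaike weight.
    """
    communities, truth = generate_collection(spec)
    records = []
    for comm, (_, t) in zip(communities, truth.iterrows()):
        fits = fit_all(comm)
        comp = compare_site(fits, comm.richness, comm.site_id)
        rec = {"site_id": comm.site_id, "family": t["family"],
               "excluded": comp.excluded,
               "best": comp.best_family,
               "weight_true": (comp.weight.get(t["family"], np.nan)
                               if not comp.excluded else np.nan)}
        for fam in FAMILY_ORDER:
            rec[f"weight_{fam}"] = (comp.weight.get(fam, np.nan)
                                    if not comp.excluded else np.nan)
        fit = comp.fits[t["family"]]
        for name, val in fit.params.items():
            true_val = t.get(f"param_{name}", np.nan)
            if pd.notna(true_val):
                rec[f"err_{name}"] = val - true_val
        records.append(rec)
    df = pd.DataFrame(records)

    out = []
    for fam in spec.families:
        sub = df[df["family"] == fam]
        inc = sub[~sub["excluded"]]
        row = {"family": fam, "n_sites": len(sub), "n_included": len(inc),
               "best_aicc_prop": (inc["best"] == fam).mean() if len(inc) else np.nan,
               "mean_weight": inc["weight_true"].mean() if len(inc) else np.nan}
        for cand in FAMILY_ORDER:
            row[f"mean_weight_{cand}"] = (inc[f"weight_{cand}"].mean()
                                          if len(inc) else np.nan)
        for col in sub.columns:
            if col.startswith("err_"):
                errs = sub[col].dropna()
                if len(errs):
                    row[f"bias_{col[4:]}"] = errs.mean()
                    row[f"rmse_{col[4:]}"] = np.sqrt((errs ** 2).mean())
        out.append(row)
    return pd.DataFrame(out).set_index("family")
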