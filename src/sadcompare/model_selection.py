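"""AICc, Akaike weights, best-model choice and log-likelihood deviations.

The AICc sample size is the number of species in the community.  Sites too
species-poor for the two-parameter models to receive an AICc (richness below
``min_richness``, default 4) are excluded from selection and carry a
machine-readable reason.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .distributions import FAMILY_ORDER
from .fitting import ModelFit

__all__ = [
    "aicc",
    "akaike_weights",
    "best_model",
    "loglik_deviation",
    "compare_site",
    "SiteComparison",
    "LoglikDeviation",
    "DEFAULT_MIN_RICHNESS",
]

DEFAULT_MIN_RICHNESS = 4
_TIE_RTOL = 1e-9


def aicc(loglik: float, K: int, n: int) -> float:
    """Corrected AIC: -2*loglik + 2K + 2K(K+1)/(n-K-1)."""
    if n - K - 1 < 1:
        raise ValueError(
            f"AICc undefined for sample size n={n} with K={K} parameters "
            f"(requires n >= K + 2)")
    return -2.0 * loglik + 2.0 * K + 2.0 * K * (K + 1) / (n - K - 1)


def akaike_weights(aiccs) -> np.ndarray:
    """Akaike weights from AICc values, via the Delta form for stability.

    Non-finite entries are excluded and get weight 0; the remaining weights
    are renormalized.
    """
    a = np.asarray(aiccs, dtype=float)
    finite = np.isfinite(a)
    if not finite.any():
        raise ValueError("no finite AICc values")
    w = np.zeros_like(a)
    delta = a[finite] - a[finite].min()
    ew = np.exp(-0.5 * delta)
    w[finite] = ew / ew.sum()
    return w


@dataclass
class SiteComparison:
    """All four fits for one site plus the AICc comparison."""

    site_id: str
    n_species: int
    fits: dict            # family -> ModelFit
    aicc: dict            # family -> AICc (np.nan when family excluded)
    delta_aicc: dict
    weight: dict
    best_family: str | None
    included: tuple       # families that received a weight
    excluded: bool = False
    exclude_reason: str = ""
    tie: bool = False
    dataset_id: str = "default"


@dataclass
class LoglikDeviation:
    site_id: str
    deviation: dict       # family -> loglik - mean(logliks)


def best_model(comparison: SiteComparison) -> str:
    """Family with the highest weight; ties go to fewer parameters, then
    canonical order. Requires >= 2 included families."""
    if comparison.excluded or len(comparison.included) < 2:
        raise ValueError(
            f"site {comparison.site_id!r} excluded from model selection "
            f"({comparison.exclude_reason or 'fewer than 2 included families'})")
    fams = list(comparison.included)
    w = np.array([comparison.weight[f] for f in fams])
    wmax = w.max()
    tied = [f for f, wi in zip(fams, w)
            if wi >= wmax - _TIE_RTOL * max(abs(wmax), 1.0)]
    if len(tied) > 1:
        comparison.tie = True
        tied.sort(key=lambda f: (comparison.fits[f].K, FAMILY_ORDER.index(f)))
    return tied[0]


def loglik_deviation(fits) -> LoglikDeviation:
    """Per-family deviation of loglik from the across-family mean."""
    if isinstance(fits, dict):
        site_id = ""
        items = [(f, fit) for f, fit in fits.items()]
    else:
        site_id = ""
        items = [(fit.family, fit) for fit in fits]
    lls = np.array([fit.loglik for _, fit in items], dtype=float)
    if not np.all(np.isfinite(lls)):
        raise ValueError("non-finite log-likelihood; site skipped for deviations")
    mean = lls.mean()
    return LoglikDeviation(site_id, {f: float(ll - mean)
                                     for (f, _), ll in zip(items, lls)})


def compare_site(fits, n_species, site_id="", dataset_id="default",
                 min_richness=DEFAULT_MIN_RICHNESS) -> SiteComparison:
    """Build the AICc comparison for one site from its four fits."""
    fit_map = {f.family: f for f in fits}
    aiccs = {}
    for fam, fit in fit_map.items():
        if n_species < min_richness or n_species - fit.K - 1 < 1:
            aiccs[fam] = np.nan
        elif not np.isfinite(fit.loglik):
            aiccs[fam] = np.nan
        else:
            aiccs[fam] = aicc(fit.loglik, fit.K, n_species)

    fams = list(fit_map)
    a = np.array([aiccs[f] for f in fams])
    included = tuple(f for f, ai in zip(fams, a) if np.isfinite(ai))

    if n_species < min_richness:
        return SiteComparison(site_id, n_species, fit_map, aiccs,
                              {f: np.nan for f in fams},
                              {f: np.nan for f in fams},
                              None, included, excluded=True,
                              exclude_reason="low_richness",
                              dataset_id=dataset_id)
    if len(included) < 2:
        return SiteComparison(site_id, n_species, fit_map, aiccs,
                              {f: np.nan for f in fams},
                              {f: np.nan for f in fams},
                              None, included, excluded=True,
                              exclude_reason="insufficient_finite_fits",
                              dataset_id=dataset_id)

    w = akaike_weights(a)
    amin = np.nanmin(a)
    delta = {f: (float(ai - amin) if np.isfinite(ai) else np.nan)
             for f, ai in zip(fams, a)}
    weight = {f: (float(wi) if np.isfinite(ai) else np.nan)
              for f, ai, wi in zip(fams, a, w)}
    comp = SiteComparison(site_id, n_species, fit_map, aiccs, delta, weight,
                          None, included, dataset_id=dataset_id)
    comp.best_family = best_model(comp)
    return comp
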