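"""Maximum-likelihood fitting of the four abundance models to one community.

Each ``fit_*`` function returns a :class:`ModelFit` and never raises on a
valid (positive-integer) abundance vector: degenerate inputs (all
singletons, zero variance, a single species) come back flagged via
``converged`` / ``at_boundary`` instead.

Likelihoods are computed per unique abundance value with multiplicity
weights, so cost scales with the number of distinct abundances rather than
species richness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats
from scipy.special import expit, logit

from .distributions import (
    FAMILY_ORDER,
    PARAM_COUNTS,
    _as_counts,
    pln_log_trunc_norm,
    pln_logpmf_untruncated,
)

__all__ = [
    "Community",
    "ModelFit",
    "fit_logseries",
    "fit_zipf",
    "fit_neg_binom",
    "fit_poisson_lognormal",
    "fit_all",
]

# boundary policy
P_LO, P_HI = 1e-10, 1.0 - 1e-10
S_LO, S_HI = 1.0 + 1e-6, 50.0
SIGMA_LO, SIGMA_HI = 1e-3, 1e2
K_LO, K_HI = 1e-6, 1e6
MU_LO, MU_HI = -50.0, 50.0
_N_RESTARTS = 3


@dataclass(frozen=True)
class Community:
    """One site's abundance vector — the unit of fitting."""

    site_id: str
    abundances: np.ndarray
    dataset_id: str = "default"

    def __post_init__(self):
        arr = _as_counts(self.abundances)
        if arr.size < 1:
            raise ValueError(f"community {self.site_id!r} has no species")
        object.__setattr__(self, "abundances", arr)

    @property
    def richness(self):
        return int(self.abundances.size)


@dataclass
class ModelFit:
    family: str
    params: dict
    loglik: float
    K: int
    converged: bool = True
    at_boundary: bool = False
    message: str = ""

    def __post_init__(self):
        assert self.K == PARAM_COUNTS[self.family]


def _unique_weighted(abundances):
    vals, cnts = np.unique(abundances, return_counts=True)
    return vals.astype(float), cnts.astype(float)


def _multistart(negll, starts, args, bounds, jitter_seed):
    """L-BFGS-B from each start, jittered restarts only if nothing converged,
    then a Nelder-Mead polish from the best point.  Deterministic."""
    best = None
    any_success = False
    for x0 in starts:
        x0 = tuple(np.clip(x, lo, hi) for x, (lo, hi) in zip(x0, bounds))
        res = optimize.minimize(negll, x0, args=args, method="L-BFGS-B",
                                bounds=bounds,
                                options={"ftol": 1e-13, "gtol": 1e-9,
                                         "maxiter": 500})
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    if not any_success:
        rng = np.random.default_rng(jitter_seed)
        for _ in range(_N_RESTARTS):
            x0 = tuple(np.clip(x + rng.normal(0, 1.0), lo, hi)
                       for x, (lo, hi) in zip(starts[0], bounds))
            res = optimize.minimize(negll, x0, args=args, method="L-BFGS-B",
                                    bounds=bounds,
                                    options={"ftol": 1e-13, "gtol": 1e-9,
                                             "maxiter": 500})
            any_success = any_success or bool(res.success)
            if res.fun < best.fun:
                best = res
    res = optimize.minimize(negll, best.x, args=args, method="Nelder-Mead",
                            options={"xatol": 1e-9, "fatol": 1e-11,
                                     "maxiter": 800})
    if res.fun <= best.fun:
        best = res
        any_success = any_success or bool(res.success)
    return best, any_success


# ---------------------------------------------------------------------------
# log-series
# ---------------------------------------------------------------------------

def logseries_loglik(p, vals, cnts):
    return float(cnts @ (vals * np.log(p) - np.log(vals))
                 - cnts.sum() * np.log(-np.log1p(-p)))


def _logseries_mean(p):
    return -p / ((1.0 - p) * np.log1p(-p))


def fit_logseries(community: Community) -> ModelFit:
    """MLE for the log-series: p solves mean(p) = sample mean."""
    vals, cnts = _unique_weighted(community.abundances)
    xbar = float(np.average(vals, weights=cnts))

    if xbar <= 1.0 + 1e-12:
        # all singletons: the MLE pushes p -> 0
        p_hat = P_LO
        return ModelFit("logseries", {"p": p_hat},
                        logseries_loglik(p_hat, vals, cnts), 1,
                        converged=True, at_boundary=True,
                        message="mean abundance 1: p at lower bound")

    lo, hi = P_LO, P_HI
    if _logseries_mean(hi) < xbar:
        p_hat = hi
        boundary = True
        msg = "sample mean above attainable range: p at upper bound"
    else:
        p_hat = optimize.brentq(lambda p: _logseries_mean(p) - xbar, lo, hi,
                                xtol=1e-14, rtol=8.9e-16)
        boundary = False
        msg = ""
    return ModelFit("logseries", {"p": float(p_hat)},
                    logseries_loglik(p_hat, vals, cnts), 1,
                    converged=True, at_boundary=boundary, message=msg)


# ---------------------------------------------------------------------------
# Zipf
# ---------------------------------------------------------------------------

def zipf_loglik(s, vals, cnts):
    return float(-s * (cnts @ np.log(vals))
                 - cnts.sum() * np.log(special.zeta(s)))


def fit_zipf(community: Community) -> ModelFit:
    vals, cnts = _unique_weighted(community.abundances)

    if np.all(vals == 1):
        # likelihood increases monotonically in s
        return ModelFit("zipf", {"s": S_HI}, zipf_loglik(S_HI, vals, cnts), 1,
                        converged=True, at_boundary=True,
                        message="all singletons: s at upper bound")

    res = optimize.minimize_scalar(
        lambda s: -zipf_loglik(s, vals, cnts),
        bounds=(S_LO, S_HI), method="bounded",
        options={"xatol": 1e-10})
    s_hat = float(res.x)
    boundary = s_hat <= S_LO + 1e-6 or s_hat >= S_HI - 1e-6
    return ModelFit("zipf", {"s": s_hat}, zipf_loglik(s_hat, vals, cnts), 1,
                    converged=bool(res.success), at_boundary=boundary,
                    message="" if res.success else str(res.message))


# ---------------------------------------------------------------------------
# zero-truncated negative binomial
# ---------------------------------------------------------------------------

def ztnb_loglik(k, q, vals, cnts):
    """Zero-truncated NB log-likelihood; stable for k down to ~1e-12."""
    log_norm = np.log(-np.expm1(k * np.log(q)))
    ll = cnts @ stats.nbinom.logpmf(vals, k, q) - cnts.sum() * log_norm
    return float(ll)


def _ztnb_negll(theta, vals, cnts):
    logk, lq = theta
    k = np.exp(logk)
    q = expit(lq)
    if not (K_LO <= k <= K_HI) or q <= 0.0 or q >= 1.0:
        return 1e12
    ll = ztnb_loglik(k, q, vals, cnts)
    return -ll if np.isfinite(ll) else 1e12


def fit_neg_binom(community: Community, logseries_p: float | None = None) -> ModelFit:
    """MLE on the (log k, logit q) scale with multi-start.

    The log-series is the k -> 0 limit of the truncated NB (with q = 1 - p),
    so a start pinned at that corner guarantees the NB never fits worse than
    the log-series.
    """
    vals, cnts = _unique_weighted(community.abundances)
    S = cnts.sum()
    xbar = float(np.average(vals, weights=cnts))
    var = float(np.average((vals - xbar) ** 2, weights=cnts)) * S / max(S - 1, 1)

    # method-of-moments (untruncated moments as a rough guide)
    q0 = np.clip(xbar / var if var > xbar else 0.7, 0.01, 0.95)
    k0 = np.clip(xbar * q0 / (1.0 - q0), 1e-3, 1e3)
    # log-series corner: the k -> 0 limit with q = 1 - p
    if logseries_p is None:
        logseries_p = fit_logseries(community).params["p"]
    q_ls = np.clip(1.0 - logseries_p, 1e-9, 1.0 - 1e-9)
    starts = [(np.log(k0), logit(q0)), (np.log(1e-5), logit(q_ls))]

    bounds = [(np.log(K_LO), np.log(K_HI)), (-34.0, 34.0)]
    best, any_success = _multistart(_ztnb_negll, starts, (vals, cnts), bounds,
                                    jitter_seed=0)

    k_hat = float(np.clip(np.exp(best.x[0]), K_LO, K_HI))
    q_hat = float(np.clip(expit(best.x[1]), 1e-12, 1.0 - 1e-12))
    ll = ztnb_loglik(k_hat, q_hat, vals, cnts)
    boundary = (k_hat <= K_LO * 1.01 or k_hat >= K_HI * 0.99
                or q_hat <= 1e-9 or q_hat >= 1.0 - 1e-9)
    degenerate = vals.size == 1
    return ModelFit(
        "neg_binom", {"k": k_hat, "q": q_hat}, ll, 2,
        converged=bool(any_success and np.isfinite(ll) and not degenerate),
        at_boundary=bool(boundary or degenerate),
        message="degenerate community (single distinct abundance)" if degenerate else "")


# ---------------------------------------------------------------------------
# zero-truncated Poisson lognormal
# ---------------------------------------------------------------------------

def ztpln_loglik(mu, sigma, vals, cnts):
    lp = pln_logpmf_untruncated(vals, mu, sigma)
    log_norm = pln_log_trunc_norm(mu, sigma)
    return float(cnts @ lp - cnts.sum() * log_norm)


def _ztpln_negll(theta, vals, cnts):
    mu, logsig = theta
    sigma = np.exp(logsig)
    ll = ztpln_loglik(mu, sigma, vals, cnts)
    return -ll if np.isfinite(ll) else 1e12


def fit_poisson_lognormal(community: Community) -> ModelFit:
    vals, cnts = _unique_weighted(community.abundances)
    logn = np.log(vals)
    mu0 = float(np.average(logn, weights=cnts))
    sd0 = float(np.sqrt(np.average((logn - mu0) ** 2, weights=cnts)))
    sig0 = np.clip(sd0 if sd0 > 0 else SIGMA_LO, SIGMA_LO, SIGMA_HI)

    # coarse profile start: the surface can be bimodal (an interior mode vs
    # a mu -> -inf ridge), so seed one start from a small candidate grid
    cand = [(m, np.log(s))
            for m in np.linspace(mu0 - 3.0, mu0 + 2.0, 6)
            for s in (0.3, 0.7, 1.2, 2.0, 3.0)]
    grid_best = min(cand, key=lambda x: _ztpln_negll(x, vals, cnts))
    starts = [(mu0, np.log(sig0)), grid_best,
              (mu0 - 0.5, np.log(max(sig0, 0.5)))]
    bounds = [(MU_LO, MU_HI), (np.log(SIGMA_LO), np.log(SIGMA_HI))]
    best, any_success = _multistart(_ztpln_negll, starts, (vals, cnts), bounds,
                                    jitter_seed=1)

    mu_hat = float(np.clip(best.x[0], MU_LO, MU_HI))
    sigma_hat = float(np.clip(np.exp(best.x[1]), SIGMA_LO, SIGMA_HI))
    ll = ztpln_loglik(mu_hat, sigma_hat, vals, cnts)
    boundary = (sigma_hat <= SIGMA_LO * 1.01 or sigma_hat >= SIGMA_HI * 0.99
                or abs(mu_hat) >= 0.99 * MU_HI)
    degenerate = vals.size == 1
    return ModelFit(
        "poisson_lognormal", {"mu": mu_hat, "sigma": sigma_hat}, ll, 2,
        converged=bool(any_success and np.isfinite(ll) and not degenerate),
        at_boundary=bool(boundary or degenerate),
        message="degenerate community (single distinct abundance)" if degenerate else "")


# ---------------------------------------------------------------------------

def fit_all(community: Community) -> list[ModelFit]:
    """Fit all four families, in the canonical order; never raises."""
    ls = fit_logseries(community)
    fits = [
        ls,
        fit_poisson_lognormal(community),
        fit_neg_binom(community, logseries_p=ls.params["p"]),
        fit_zipf(community),
    ]
    order = [f.family for f in fits]
    assert tuple(order) == FAMILY_ORDER
    return fits
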