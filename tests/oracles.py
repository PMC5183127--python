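"""Independent oracles used by the test suite.

Exhaustive grid searches over the likelihood surfaces, written directly
against the distribution formulas (not the package's fitting code), so that
MLE results can be checked against a path-independent reference.
"""

import numpy as np
from scipy import special, stats


def _weighted(abundances):
    vals, cnts = np.unique(np.asarray(abundances), return_counts=True)
    return vals.astype(float), cnts.astype(float)


def grid_max_logseries(abundances, step=1e-5):
    """Max log-likelihood of the log-series over a p grid."""
    vals, cnts = _weighted(abundances)
    S = cnts.sum()
    sum_n = cnts @ vals
    sum_logn = cnts @ np.log(vals)
    p = np.arange(step, 1.0, step)
    ll = sum_n * np.log(p) - sum_logn - S * np.log(-np.log1p(-p))
    i = np.argmax(ll)
    return float(ll[i]), float(p[i])


def grid_max_zipf(abundances, step=1e-3, s_max=50.0):
    """Max log-likelihood of the zeta distribution over an s grid."""
    vals, cnts = _weighted(abundances)
    S = cnts.sum()
    sum_logn = cnts @ np.log(vals)
    s = np.arange(1.0 + step, s_max, step)
    ll = -s * sum_logn - S * np.log(special.zeta(s))
    i = np.argmax(ll)
    return float(ll[i]), float(s[i])


def grid_max_ztnb(abundances, n_grid=100):
    """Max zero-truncated NB log-likelihood over a (k, q) grid."""
    vals, cnts = _weighted(abundances)
    S = cnts.sum()
    k = np.logspace(-3, 3, n_grid)
    q = np.linspace(0.005, 0.995, n_grid)
    kk, qq = np.meshgrid(k, q, indexing="ij")
    kf = kk.ravel()[:, None]
    qf = qq.ravel()[:, None]
    ll = (cnts[None, :] * stats.nbinom.logpmf(vals[None, :], kf, qf)).sum(axis=1)
    ll -= S * np.log(-np.expm1(kf[:, 0] * np.log(qf[:, 0])))
    i = np.argmax(ll)
    return float(ll[i]), (float(kf[i, 0]), float(qf[i, 0]))


def pln_pmf_trapezoid(n, mu, sigma, n_nodes=2000):
    """Untruncated Poisson-lognormal pmf by brute-force trapezoid on log-rate.

    Independent of the package's mode-centred Gauss-Hermite scheme; only
    valid where the node spacing resolves the lognormal width (sigma well
    above the spacing), which the callers ensure.
    """
    n = np.asarray(n, dtype=float)
    lo = mu - 12 * sigma
    hi = max(mu + 12 * sigma, np.log(n.max() + 1) + 5)
    u = np.linspace(lo, hi, n_nodes)
    lam = np.exp(u)
    log_poisson = (n[:, None] * u[None, :] - lam[None, :]
                   - special.gammaln(n[:, None] + 1))
    log_norm = (-0.5 * ((u - mu) / sigma) ** 2
                - np.log(sigma) - 0.5 * np.log(2 * np.pi))
    integrand = np.exp(log_poisson + log_norm[None, :])
    return np.trapezoid(integrand, u, axis=1)


def grid_max_ztpln(abundances, n_grid=100):
    """Max zero-truncated PLN log-likelihood over a (mu, sigma) grid.

    Grid search on the quadrature likelihood: the exhaustive search is the
    independent check on the optimizer; the quadrature itself is validated
    separately against mpmath and trapezoid references.
    """
    from sadcompare.distributions import pln_logpmf_untruncated

    vals, cnts = _weighted(abundances)
    S = cnts.sum()
    n_ext = np.append(vals, 0.0)
    mus = np.linspace(-5.0, 5.0, n_grid)
    sigmas = np.linspace(0.05, 4.0, n_grid)
    best = (-np.inf, None)
    for sigma in sigmas:
        lp = pln_logpmf_untruncated(n_ext[None, :], mus[:, None], sigma)
        log_norm = np.log1p(-np.exp(lp[:, -1]))
        ll = lp[:, :-1] @ cnts - S * log_norm
        i = int(np.argmax(ll))
        if ll[i] > best[0]:
            best = (float(ll[i]), (float(mus[i]), float(sigma)))
    return best
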