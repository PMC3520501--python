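"""Log-normal-normal (NN) model: closed-form marginals and posterior draws.

All computations happen on the natural-log scale; callers pass raw positive
expression values and this module transforms internally.

Under the default conjugate ("generalized variance") mean prior
``mu | sigma^2 ~ N(mu0, tau0^2 sigma^2)`` the marginal likelihood of a gene's
observations, with the means and variance integrated out, is a multivariate
Student-t:

    y ~ t_{nu0}( mu0 * 1,  sigma0^2 * (I + tau0^2 * Z Z') )

where Z is the sample-to-mean-group indicator matrix (one mean shared by both
groups under EE, one mean per group under DE; the variance sigma_i^2 is shared
either way).  The determinant and quadratic form factor over mean groups,
which is what the vectorised routines below exploit.

Under ``mean_prior="independent"`` (``mu ~ N(mu0, tau0^2)``, no sigma^2
coupling) the mean is still conjugate given sigma^2 but sigma^2 must be
integrated numerically; a fixed-node Gauss-Legendre rule on log sigma^2 over
the central prior mass is used.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .params import NNHyperParams

__all__ = [
    "group_stats",
    "log_marginal_patterns",
    "posterior_mean_params",
    "sample_posterior_params",
]


def _to_log(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.size and np.any(x <= 0):
        raise ValueError("NN model requires strictly positive values (log scale)")
    return np.log(x)


def group_stats(y: np.ndarray) -> tuple[int, np.ndarray, np.ndarray]:
    """Per-gene count, mean and centred sum of squares of an (n, k) log matrix."""
    k = y.shape[1]
    if k == 0:
        n = y.shape[0]
        return 0, np.zeros(n), np.zeros(n)
    ybar = y.mean(axis=1)
    ss = ((y - ybar[:, None]) ** 2).sum(axis=1)
    return k, ybar, ss


def _pooled(stats0, stats1):
    k0, m0, ss0 = stats0
    k1, m1, ss1 = stats1
    k = k0 + k1
    if k == 0:
        return 0, m0, ss0
    m = (k0 * m0 + k1 * m1) / k
    ss = ss0 + ss1 + k0 * (m0 - m) ** 2 + k1 * (m1 - m) ** 2
    return k, m, ss


def _mvt_log_marginal(groups, hyper: NNHyperParams) -> np.ndarray:
    """Closed-form log marginal for a set of mean groups sharing sigma^2
    (conjugate scaled mean prior)."""
    nu0, s0sq, t0sq = hyper.nu0, hyper.sigma0**2, hyper.tau0**2
    ktot = sum(g[0] for g in groups)
    if ktot == 0:
        return np.zeros_like(groups[0][1])
    logdet = 0.0
    q = np.zeros_like(groups[0][1])
    for k, ybar, ss in groups:
        if k == 0:
            continue
        logdet += np.log1p(k * t0sq)
        q = q + ss + k * (ybar - hyper.mu0) ** 2 / (1.0 + k * t0sq)
    return (
        gammaln((nu0 + ktot) / 2.0)
        - gammaln(nu0 / 2.0)
        - 0.5 * ktot * np.log(nu0 * np.pi * s0sq)
        - 0.5 * logdet
        - 0.5 * (nu0 + ktot) * np.log1p(q / (nu0 * s0sq))
    )


def _sigma2_nodes(hyper: NNHyperParams, n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Legendre nodes/log-weights for integrating against the
    Scaled-Inv-chi^2(nu0, sigma0^2) prior on log sigma^2."""
    prior = stats.invgamma(hyper.nu0 / 2.0, scale=hyper.nu0 * hyper.sigma0**2 / 2.0)
    lo, hi = np.log(prior.ppf([1e-4, 1.0 - 1e-4]))
    u, w = np.polynomial.legendre.leggauss(n_nodes)
    logs2 = 0.5 * (hi - lo) * u + 0.5 * (hi + lo)
    s2 = np.exp(logs2)
    # weight includes the Jacobian of sigma^2 = exp(u) and the prior density
    logw = np.log(w * 0.5 * (hi - lo)) + prior.logpdf(s2) + logs2
    return s2, logw


def _quad_log_marginal(groups, hyper: NNHyperParams, n_nodes: int) -> np.ndarray:
    """Independent mean prior N(mu0, tau0^2): integrate sigma^2 by quadrature."""
    t0sq = hyper.tau0**2
    s2, logw = _sigma2_nodes(hyper, n_nodes)  # (Q,), (Q,)
    ktot = sum(g[0] for g in groups)
    if ktot == 0:
        return np.zeros_like(groups[0][1])
    # log N(y | mu0 1, s2 I + t0sq J) per group, (n, Q)
    total = np.zeros((groups[0][1].shape[0], s2.shape[0]))
    for k, ybar, ss in groups:
        if k == 0:
            continue
        denom = s2 + k * t0sq  # (Q,)
        quad = ss[:, None] / s2[None, :] + k * (ybar[:, None] - hyper.mu0) ** 2 / denom
        logdet = (k - 1) * np.log(s2) + np.log(denom)
        total += -0.5 * (k * np.log(2 * np.pi) + logdet + quad)
    return _logsumexp(total + logw[None, :], axis=1)


def _logsumexp(a: np.ndarray, axis: int) -> np.ndarray:
    amax = np.max(a, axis=axis, keepdims=True)
    out = amax.squeeze(axis) + np.log(np.sum(np.exp(a - amax), axis=axis))
    return out


def log_marginal_patterns(
    x0: np.ndarray,
    x1: np.ndarray,
    hyper: NNHyperParams,
    *,
    mean_prior: str = "scaled",
    n_nodes: int = 64,
) -> tuple[np.ndarray, np.ndarray]:
    """Log marginal densities (EE, DE) per gene.

    Parameters
    ----------
    x0, x1
        Positive raw-scale matrices of shape ``(n, k0)`` and ``(n, k1)``; one
        may have zero columns, in which case the two patterns coincide.
    mean_prior
        ``"scaled"`` (conjugate, closed form) or ``"independent"`` (1-D
        quadrature over sigma^2).
    """
    y0, y1 = _to_log(x0), _to_log(x1)
    if y0.shape[1] == 0 and y1.shape[1] == 0:
        raise ValueError("gene has no observations in either group")
    g0, g1 = group_stats(y0), group_stats(y1)
    pooled = _pooled(g0, g1)
    if mean_prior == "scaled":
        ee = _mvt_log_marginal([pooled], hyper)
        de = _mvt_log_marginal([g0, g1], hyper)
    elif mean_prior == "independent":
        ee = _quad_log_marginal([pooled], hyper, n_nodes)
        de = _quad_log_marginal([g0, g1], hyper, n_nodes)
    else:
        raise ValueError(f"unknown mean_prior {mean_prior!r}")
    return ee, de


def posterior_mean_params(
    x0: np.ndarray, x1: np.ndarray, hyper: NNHyperParams
) -> dict[str, np.ndarray]:
    """Normal-Inv-chi^2 posterior blocks under both patterns (scaled prior).

    Returns the posterior mean/precision of each mean group and the
    Scaled-Inv-chi^2 posterior (df, scale^2) of sigma^2, for EE and DE.
    """
    y0, y1 = _to_log(x0), _to_log(x1)
    g0, g1 = group_stats(y0), group_stats(y1)
    pooled = _pooled(g0, g1)
    kappa0 = 1.0 / hyper.tau0**2
    nu0, s0sq = hyper.nu0, hyper.sigma0**2
    n = y0.shape[0]

    def mean_block(k, ybar):
        kappa_n = kappa0 + k
        mu_n = (kappa0 * hyper.mu0 + k * ybar) / kappa_n
        return mu_n, kappa_n

    def var_contrib(k, ybar, ss):
        if k == 0:
            return np.zeros(n)
        return ss + (kappa0 * k / (kappa0 + k)) * (ybar - hyper.mu0) ** 2

    out: dict[str, np.ndarray] = {}
    ktot = g0[0] + g1[0]
    # EE: one pooled mean
    mu_n, kappa_n = mean_block(pooled[0], pooled[1])
    out["ee_mu_n"], out["ee_kappa_n"] = mu_n, np.full(n, kappa_n)
    out["ee_nu_n"] = np.full(n, nu0 + ktot)
    out["ee_nu_s2"] = nu0 * s0sq + var_contrib(*pooled)
    # DE: one mean per group, shared sigma^2
    for label, g in (("0", g0), ("1", g1)):
        mu_n, kappa_n = mean_block(g[0], g[1])
        out[f"de_mu_n{label}"] = mu_n
        out[f"de_kappa_n{label}"] = np.full(n, kappa_n)
    out["de_nu_n"] = np.full(n, nu0 + ktot)
    out["de_nu_s2"] = nu0 * s0sq + var_contrib(*g0) + var_contrib(*g1)
    return out


def sample_posterior_params(
    x0: np.ndarray,
    x1: np.ndarray,
    hyper: NNHyperParams,
    delta: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (mu_i0, mu_i1, sigma_i^2) from the pattern-conditional posterior.

    Returns ``(group_means, var)`` with shapes ``(n, 2)`` and ``(n,)``.
    """
    post = posterior_mean_params(x0, x1, hyper)
    n = delta.shape[0]
    de = delta.astype(bool)
    nu_n = np.where(de, post["de_nu_n"], post["ee_nu_n"])
    nu_s2 = np.where(de, post["de_nu_s2"], post["ee_nu_s2"])
    var = nu_s2 / rng.chisquare(nu_n)
    sd = np.sqrt(var)
    means = np.empty((n, 2))
    mu_ee = post["ee_mu_n"] + sd / np.sqrt(post["ee_kappa_n"]) * rng.standard_normal(n)
    means[:, 0] = np.where(
        de,
        post["de_mu_n0"] + sd / np.sqrt(post["de_kappa_n0"]) * rng.standard_normal(n),
        mu_ee,
    )
    means[:, 1] = np.where(
        de,
        post["de_mu_n1"] + sd / np.sqrt(post["de_kappa_n1"]) * rng.standard_normal(n),
        mu_ee,
    )
    return means, var
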