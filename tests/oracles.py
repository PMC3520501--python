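"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — dense-grid quadrature, exhaustive
enumeration, plain Python loops — and shares no code path with the package
internals it checks.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import stats
from scipy.integrate import simpson


def _log_simpson(log_f: np.ndarray, x: np.ndarray) -> float:
    """log of a Simpson integral of exp(log_f) along x, stably."""
    m = log_f.max()
    return m + np.log(simpson(np.exp(log_f - m), x=x))


def nn_log_marginal(x0, x1, hyper, pattern, mean_prior="scaled") -> float:
    """Dense 2-D grid quadrature over (mean, variance) for one gene (NN)."""
    y0, y1 = np.log(np.asarray(x0, float)), np.log(np.asarray(x1, float))
    nu0, s0sq, t0 = hyper.nu0, hyper.sigma0**2, hyper.tau0
    prior_s2 = stats.invgamma(nu0 / 2.0, scale=nu0 * s0sq / 2.0)
    log_s2 = np.linspace(*np.log(prior_s2.ppf([1e-8, 1 - 1e-8])), 600)
    s2 = np.exp(log_s2)  # (S,)
    u = np.linspace(-12.0, 12.0, 1201)  # standardised mean grid

    def group_int(y: np.ndarray) -> np.ndarray:
        """integral over the group mean, per s2 node -> (S,) in log."""
        if y.size == 0:
            return np.zeros_like(s2)
        sd_mu = t0 * np.sqrt(s2) if mean_prior == "scaled" else np.full_like(s2, t0)
        mu = hyper.mu0 + sd_mu[:, None] * u[None, :]  # (S, U)
        ll = stats.norm.logpdf(
            y[None, None, :], mu[:, :, None], np.sqrt(s2)[:, None, None]
        ).sum(axis=2)
        integrand = ll + stats.norm.logpdf(u)[None, :]
        m = integrand.max(axis=1, keepdims=True)
        return m[:, 0] + np.log(simpson(np.exp(integrand - m), x=u, axis=1))

    if pattern == "EE":
        log_inner = group_int(np.concatenate([y0, y1]))
    else:
        log_inner = group_int(y0) + group_int(y1)
    # log-spaced s2 grid: include the Jacobian s2
    log_f = log_inner + prior_s2.logpdf(s2) + log_s2
    return float(_log_simpson(log_f, log_s2))


def gaga_log_marginal(x0, x1, hyper, pattern) -> float:
    """Dense 2-D grid quadrature over (inverse mean, shape) for one gene."""
    x0, x1 = np.asarray(x0, float), np.asarray(x1, float)
    prior_a = stats.gamma(hyper.beta, scale=hyper.mu / hyper.beta)
    prior_r = stats.gamma(hyper.alpha0, scale=hyper.nu / hyper.alpha0)
    log_a = np.linspace(*np.log(prior_a.ppf([1e-8, 1 - 1e-8])), 500)
    # the r grid must cover the likelihood (centred near 1/x) as well as
    # the prior, otherwise low-expression genes lose posterior mass
    x_all = np.concatenate([np.atleast_1d(x0), np.atleast_1d(x1)])
    r_lo = min(prior_r.ppf(1e-9), 1e-3 / x_all.max())
    r_hi = max(prior_r.ppf(1 - 1e-9), 1e3 / x_all.min())
    log_r = np.linspace(np.log(r_lo), np.log(r_hi), 1200)
    a, r = np.exp(log_a), np.exp(log_r)

    def group_int(x: np.ndarray) -> np.ndarray:
        """integral over the inverse mean r per shape node -> (A,) in log."""
        if x.size == 0:
            return np.zeros_like(a)
        # x ~ Ga(a, rate a*r)
        ll = (
            stats.gamma.logpdf(
                x[None, None, :], a[:, None, None],
                scale=1.0 / (a[:, None, None] * r[None, :, None]),
            ).sum(axis=2)
        )
        log_f = ll + prior_r.logpdf(r)[None, :] + log_r[None, :]
        m = log_f.max(axis=1, keepdims=True)
        return m[:, 0] + np.log(simpson(np.exp(log_f - m), x=log_r, axis=1))

    if pattern == "EE":
        log_inner = group_int(np.concatenate([x0, x1]))
    else:
        log_inner = group_int(x0) + group_int(x1)
    log_f = log_inner + prior_a.logpdf(a) + log_a
    return float(_log_simpson(log_f, log_a))


def max_discoveries(v: np.ndarray, level: float) -> int:
    """Exhaustive search: the largest D with posterior expected FDR <= level."""
    v = np.asarray(v, float)
    n = v.size
    best = 0
    for mask in itertools.product([0, 1], repeat=n):
        d = np.array(mask)
        D = d.sum()
        if D == 0 or D <= best:
            continue
        if np.sum((1 - v) * d) / D <= level:
            best = D
    return int(best)


def boundary_utilities(delta, etp_at, t0, T, c, grid):
    """Straightforward re-implementation of boundary evaluation.

    Returns {(b0, b1): mean utility} computed with plain loops.
    """
    out = {}
    B = delta.shape[0]
    for b0, b1 in grid:
        total = 0.0
        for j in range(B):
            tau = None
            for k in range(t0, T - 1):
                if delta[j, k - t0] <= b0 + b1 * k:
                    tau = k
                    break
            if tau is None:
                tau = T - 1 if delta[j, T - 1 - t0] - c <= 0 else T
            total += etp_at[j, tau - t0] - c * tau
        out[(b0, b1)] = total / B
    return out


def max_discoveries_fast(v: np.ndarray, level: float) -> int:
    """Vectorised exhaustive search over all 2^n decision vectors."""
    v = np.asarray(v, float)
    n = v.size
    masks = (
        (np.arange(2**n)[:, None] >> np.arange(n)[None, :]) & 1
    ).astype(float)
    D = masks.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fdr = masks @ (1.0 - v) / np.where(D > 0, D, 1.0)
    ok = (D == 0) | (fdr <= level + 1e-12)
    return int(D[ok].max())
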