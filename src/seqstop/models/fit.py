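"""Empirical-Bayes hyperparameter estimation.

``fit_hyperparameters`` maximises the marginal mixture likelihood

    l(omega) = sum_i log[ pi * m_DE(x_i | omega) + (1 - pi) * m_EE(x_i | omega) ]

by EM, treating the per-gene DE indicators as missing data.  The E-step
computes the posterior DE probabilities v_i under the current omega; the
M-step updates pi in closed form (mean of v_i) and the remaining block by
bounded numerical maximisation of the weighted complete-data log-likelihood
(a generalised M-step: the update is kept only when it improves the
objective, which preserves EM's monotonicity up to numerical tolerance).

``adjust_pi`` profiles the marginal likelihood in pi alone, holding the other
hyperparameters fixed.  This corrects the upward bias of moment-style pi
estimates: iterating pi <- mean(v_i(pi)) converges to the profile maximiser
because the mixture log-likelihood is concave in pi.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from ..batch import ExpressionBatch
from .marginals import log_marginal_matrix
from .params import GaGaHyperParams, HyperParams, NNHyperParams, hyper_for_model

__all__ = ["FitResult", "fit_hyperparameters", "adjust_pi"]

_MIN_PI, _MAX_PI = 1e-6, 1.0 - 1e-6


@dataclass(frozen=True)
class FitResult:
    """Outcome of an EM fit: the estimate plus convergence diagnostics."""

    hyper: HyperParams
    n_iter: int
    log_likelihood: float
    trace: tuple[float, ...]
    converged: bool


def _mixture_ll(ee: np.ndarray, de: np.ndarray, pi: float) -> float:
    return float(np.sum(np.logaddexp(np.log(pi) + de, np.log1p(-pi) + ee)))


def _responsibilities(ee: np.ndarray, de: np.ndarray, pi: float) -> np.ndarray:
    a = np.log(pi) + de
    b = np.log1p(-pi) + ee
    return np.exp(a - np.logaddexp(a, b))


# -- parameter packing ------------------------------------------------------


def _pack(hyper: HyperParams) -> np.ndarray:
    if isinstance(hyper, NNHyperParams):
        return np.array(
            [hyper.mu0, np.log(hyper.tau0), np.log(hyper.nu0), np.log(hyper.sigma0)]
        )
    return np.log([hyper.alpha0, hyper.nu, hyper.beta, hyper.mu])


def _unpack(theta: np.ndarray, template: HyperParams, pi: float) -> HyperParams:
    if isinstance(template, NNHyperParams):
        return NNHyperParams(
            mu0=theta[0],
            tau0=np.exp(theta[1]),
            nu0=np.exp(theta[2]),
            sigma0=np.exp(theta[3]),
            pi=pi,
        )
    a0, nu, beta, mu = np.exp(theta)
    return GaGaHyperParams(alpha0=a0, nu=nu, beta=beta, mu=mu, pi=pi)


# -- moment initialisation --------------------------------------------------


def _init_nn(x0: np.ndarray, x1: np.ndarray) -> NNHyperParams:
    y0, y1 = np.log(x0), np.log(x1)
    y = np.hstack([y0, y1])
    j = y.shape[1]
    ybar = y.mean(axis=1)
    ss_w = ((y0 - y0.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (y1 - y1.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    df = max(j - 2, 1)
    s2 = ss_w / df
    m1 = float(np.mean(s2))
    nu0 = 4.0
    sigma0 = float(np.sqrt(max(m1 * (nu0 - 2.0) / nu0, 1e-6)))
    tau2 = max((np.var(ybar) - m1 / j) / m1, 0.01)
    return NNHyperParams(
        mu0=float(np.mean(ybar)), tau0=float(np.sqrt(tau2)), nu0=nu0,
        sigma0=sigma0, pi=0.1,
    )


def _init_gaga(x0: np.ndarray, x1: np.ndarray) -> GaGaHyperParams:
    x = np.hstack([x0, x1])
    xbar = x.mean(axis=1)
    s2 = x.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        shape_hat = np.clip(xbar**2 / np.maximum(s2, 1e-12), 0.05, 1e4)
    mu = float(np.clip(np.median(shape_hat), 0.1, 1e3))
    r_hat = 1.0 / xbar
    nu = float(np.mean(r_hat))
    var_r = float(np.var(r_hat))
    alpha0 = float(np.clip(nu**2 / max(var_r, 1e-12), 0.1, 100.0))
    return GaGaHyperParams(alpha0=alpha0, nu=nu, beta=2.0, mu=mu, pi=0.1)


# -- main entry points ------------------------------------------------------


def fit_hyperparameters(
    batch: ExpressionBatch,
    model_id: str,
    *,
    max_iter: int = 200,
    tol: float = 1e-6,
    n_nodes: int = 64,
    min_genes: int = 50,
    init: HyperParams | None = None,
) -> FitResult:
    """EM estimate of the model hyperparameters from an expression batch.

    Deterministic given the data and options.  Requires at least two samples
    per group and (by default) at least 50 genes for stable estimation; genes
    with non-finite values are excluded from the fit, genes that are constant
    across all samples are rejected with their identifiers.
    """
    k0, k1 = batch.samples_per_group()
    if min(k0, k1) < 2:
        raise ValueError(f"need >= 2 samples per group for fitting, have {k0}+{k1}")
    finite = np.all(np.isfinite(batch.values), axis=1)
    values = batch.values[finite]
    gene_ids = np.asarray(batch.gene_ids)[finite]
    if values.shape[0] < min_genes:
        raise ValueError(
            f"need >= {min_genes} genes with finite values, have {values.shape[0]}"
        )
    constant = values.std(axis=1) == 0
    if np.any(constant):
        raise ValueError(
            f"constant genes cannot be fit: {gene_ids[constant][:10].tolist()}"
        )
    x0 = values[:, batch.groups == 0]
    x1 = values[:, batch.groups == 1]

    if init is None:
        hyper = _init_nn(x0, x1) if model_id == "nn" else _init_gaga(x0, x1)
    else:
        hyper = hyper_for_model(init, model_id)
    pi = float(np.clip(hyper.pi, _MIN_PI, _MAX_PI))
    theta = _pack(hyper)

    def patterns(th: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        h = _unpack(th, hyper, pi)
        return log_marginal_matrix(x0, x1, h, model_id, n_nodes=n_nodes)

    ee, de = patterns(theta)
    trace = [_mixture_ll(ee, de, pi)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        v = _responsibilities(ee, de, pi)
        pi = float(np.clip(v.mean(), _MIN_PI, _MAX_PI))

        def neg_q(th: np.ndarray) -> float:
            try:
                ee_t, de_t = patterns(th)
            except (ValueError, FloatingPointError):
                return 1e12
            return -float(np.sum(v * de_t + (1.0 - v) * ee_t))

        res = optimize.minimize(
            neg_q, theta, method="L-BFGS-B", options={"maxiter": 40}
        )
        if -res.fun > -neg_q(theta):
            theta = res.x
        ee, de = patterns(theta)
        ll = _mixture_ll(ee, de, pi)
        trace.append(ll)
        if abs(ll - trace[-2]) / (abs(trace[-2]) + 1.0) < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"EM did not converge in {max_iter} iterations "
            f"(last relative change {abs(trace[-1] - trace[-2]):.3g}); "
            "returning best iterate",
            RuntimeWarning,
        )
    return FitResult(
        hyper=_unpack(theta, hyper, pi),
        n_iter=it,
        log_likelihood=trace[-1],
        trace=tuple(trace),
        converged=converged,
    )


def adjust_pi(
    batch: ExpressionBatch,
    hyper: NNHyperParams | GaGaHyperParams,
    model_id: str = "nn",
    *,
    tol: float = 1e-8,
    max_iter: int = 500,
    n_nodes: int = 64,
) -> HyperParams:
    """Replace pi by the maximiser of the profile marginal likelihood.

    All other hyperparameters are held fixed; useful after moment-style fits
    that tend to overestimate the DE fraction.
    """
    hyper_for_model(hyper, model_id)
    x0, x1 = batch.values_by_group()
    ee, de = log_marginal_matrix(x0, x1, hyper, model_id, n_nodes=n_nodes)
    pi = float(np.clip(hyper.pi, _MIN_PI, _MAX_PI))
    for _ in range(max_iter):
        new_pi = float(np.clip(_responsibilities(ee, de, pi).mean(), 0.0, 1.0))
        if abs(new_pi - pi) < tol:
            pi = new_pi
            break
        pi = float(np.clip(new_pi, _MIN_PI, _MAX_PI))
    return hyper.with_pi(pi)
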