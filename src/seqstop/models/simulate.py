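"""Prior and posterior-predictive simulation for both analysis models.

These routines are first-class: they define the generative study conditions
used by the sequential engine (forward simulation), the study simulator and
the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .._rng import as_rng
from ..batch import ExpressionBatch
from . import gaga, lnn
from .params import (
    GaGaHyperParams,
    GeneParams,
    HyperParams,
    NNHyperParams,
    SyntheticDataset,
    hyper_for_model,
)

__all__ = ["PredictiveDraw", "sample_from_prior", "sample_posterior_predictive"]


@dataclass(frozen=True)
class PredictiveDraw:
    """New sample columns drawn from the (prior or posterior) predictive."""

    values: np.ndarray  # (n_genes, k_new)
    groups: np.ndarray  # (k_new,)
    params: GeneParams | None = None  # the theta draws behind the values


def _batch_columns(samples_per_group: tuple[int, int], n_batches: int):
    """Group labels and batch indices laid out batch-by-batch."""
    k0, k1 = samples_per_group
    if k0 < 0 or k1 < 0 or k0 + k1 == 0:
        raise ValueError("each batch needs at least one sample overall")
    one = np.concatenate([np.zeros(k0, dtype=int), np.ones(k1, dtype=int)])
    groups = np.tile(one, n_batches)
    batch_index = np.repeat(np.arange(1, n_batches + 1), k0 + k1)
    return groups, batch_index


def _draw_prior_params(
    hyper: HyperParams, model_id: str, n: int, rng: np.random.Generator
) -> GeneParams:
    delta = (rng.random(n) < hyper.pi).astype(int)
    de = delta.astype(bool)
    means = np.empty((n, 2))
    if model_id == "gaga":
        h: GaGaHyperParams = hyper  # type: ignore[assignment]
        shape_or_var = rng.gamma(h.beta, h.mu / h.beta, size=n)
        rate0 = h.alpha0 / h.nu
        lam_shared = 1.0 / rng.gamma(h.alpha0, 1.0 / rate0, size=n)
        for col in (0, 1):
            lam_own = 1.0 / rng.gamma(h.alpha0, 1.0 / rate0, size=n)
            means[:, col] = np.where(de, lam_own, lam_shared)
    else:
        hn: NNHyperParams = hyper  # type: ignore[assignment]
        shape_or_var = hn.nu0 * hn.sigma0**2 / rng.chisquare(hn.nu0, size=n)
        sd_mean = hn.tau0 * np.sqrt(shape_or_var)
        mu_shared = hn.mu0 + sd_mean * rng.standard_normal(n)
        for col in (0, 1):
            mu_own = hn.mu0 + sd_mean * rng.standard_normal(n)
            means[:, col] = np.where(de, mu_own, mu_shared)
    return GeneParams(delta=delta, group_means=means, shape_or_var=shape_or_var)


def _sample_values(
    model_id: str,
    params: GeneParams,
    groups: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    n = params.n_genes
    k = groups.shape[0]
    means = params.group_means[:, groups]  # (n, k)
    if model_id == "gaga":
        shape = params.shape_or_var[:, None]
        return rng.gamma(np.broadcast_to(shape, (n, k)), means / shape)
    sd = np.sqrt(params.shape_or_var)[:, None]
    return np.exp(means + sd * rng.standard_normal((n, k)))


def sample_from_prior(
    hyper: HyperParams,
    model_id: str,
    n: int,
    samples_per_group: tuple[int, int],
    rng_seed: int | np.random.Generator | None = None,
    *,
    n_batches: int = 1,
    gene_ids: np.ndarray | None = None,
) -> SyntheticDataset:
    """Draw a complete synthetic dataset from the hierarchical prior.

    Per gene: delta_i ~ Bernoulli(pi); theta_i from the hierarchical prior
    with the group means tied when delta_i = 0; then ``n_batches`` batches of
    ``samples_per_group`` observations from the sampling distribution.
    """
    hyper_for_model(hyper, model_id)
    if n < 1:
        raise ValueError("need at least one gene")
    rng = as_rng(rng_seed)
    groups, batch_index = _batch_columns(samples_per_group, n_batches)
    params = _draw_prior_params(hyper, model_id, n, rng)
    values = _sample_values(model_id, params, groups, rng)
    if gene_ids is None:
        gene_ids = np.array([f"g{i:05d}" for i in range(n)])
    batch = ExpressionBatch(
        values=values, groups=groups, batch_index=batch_index, gene_ids=gene_ids
    )
    return SyntheticDataset(batch=batch, truth=params, generating_hyper=hyper)


def sample_posterior_predictive(
    batch: ExpressionBatch,
    hyper: HyperParams,
    model_id: str,
    new_samples_per_group: tuple[int, int],
    rng_seed: int | np.random.Generator | None = None,
    *,
    n_nodes: int = 64,
) -> PredictiveDraw:
    """Composition sampling of one new batch from P(x_new | observed data).

    Per gene: delta_i ~ Bernoulli(v_i) with v_i the posterior DE probability,
    theta_i from its pattern-conditional posterior, then new observations from
    the sampling distribution.  With an empty batch (t = 0) this reduces
    exactly to :func:`sample_from_prior` — the same draw path is used, so a
    shared seed yields identical values.
    """
    from .marginals import posterior_de_prob  # local import avoids cycle

    hyper_for_model(hyper, model_id)
    rng = as_rng(rng_seed)
    groups, _ = _batch_columns(new_samples_per_group, 1)
    if batch.n_samples == 0:
        params = _draw_prior_params(hyper, model_id, batch.n_genes, rng)
        values = _sample_values(model_id, params, groups, rng)
        return PredictiveDraw(values=values, groups=groups, params=params)

    v = posterior_de_prob(batch, hyper, model_id, n_nodes=n_nodes)
    delta = (rng.random(batch.n_genes) < v).astype(int)
    x0, x1 = batch.values_by_group()
    if model_id == "gaga":
        means, alpha = gaga.sample_posterior_params(
            x0, x1, hyper, delta, rng, n_nodes=n_nodes
        )
        params = GeneParams(delta=delta, group_means=means, shape_or_var=alpha)
    else:
        means, var = lnn.sample_posterior_params(x0, x1, hyper, delta, rng)
        params = GeneParams(delta=delta, group_means=means, shape_or_var=var)
    values = _sample_values(model_id, params, groups, rng)
    return PredictiveDraw(values=values, groups=groups, params=params)
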