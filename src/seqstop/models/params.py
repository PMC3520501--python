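"""Hyperparameter and per-gene parameter containers for the two models.

Both analysis models are two-component mixtures over a latent differential-
expression (DE) indicator delta_i ~ Bernoulli(pi):

* GaGa — gamma observations ``x_ij ~ Ga(alpha_i, alpha_i / lambda_{i z_j})``
  (shape/rate, so ``E x = lambda``) with a conjugate gamma prior on the inverse
  mean, ``1/lambda ~ Ga(alpha0, alpha0/nu)`` (mean ``nu``), and a gamma prior
  on the gene shape, ``alpha_i ~ Ga(beta, beta/mu)`` (mean ``mu``).  Under
  delta_i = 0 the two groups share one lambda; under delta_i = 1 each group has
  its own, drawn independently, with alpha_i shared.

* NN — log-normal observations; on the log scale ``y_ij ~ N(mu_{i z_j},
  sigma_i^2)`` with ``sigma_i^2 ~ Scaled-Inv-chi^2(nu0, sigma0^2)`` and the
  conjugate mean prior ``mu_{ik} | sigma_i^2 ~ N(mu0, tau0^2 sigma_i^2)``
  ("generalized variance").  A variance-independent mean prior
  ``mu_{ik} ~ N(mu0, tau0^2)`` is available via ``mean_prior="independent"``
  on the marginal-likelihood routines.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Union

import numpy as np

__all__ = [
    "GaGaHyperParams",
    "NNHyperParams",
    "HyperParams",
    "GeneParams",
    "SyntheticDataset",
    "hyper_for_model",
]


def _check_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not np.isfinite(value) or value <= 0:
            raise ValueError(f"{name} must be strictly positive, got {value}")


def _check_pi(pi: float) -> None:
    if not 0.0 <= pi <= 1.0:
        raise ValueError(f"pi must lie in [0, 1], got {pi}")


@dataclass(frozen=True)
class GaGaHyperParams:
    """Hyperparameters (alpha0, nu, beta, mu, pi) of the GaGa hierarchy."""

    alpha0: float
    nu: float
    beta: float
    mu: float
    pi: float

    def __post_init__(self) -> None:
        _check_positive(alpha0=self.alpha0, nu=self.nu, beta=self.beta, mu=self.mu)
        _check_pi(self.pi)

    def with_pi(self, pi: float) -> "GaGaHyperParams":
        return replace(self, pi=pi)


@dataclass(frozen=True)
class NNHyperParams:
    """Hyperparameters (mu0, tau0, nu0, sigma0, pi) of the log-normal-normal
    hierarchy.  ``sigma0`` is the scale (not variance) of the
    Scaled-Inv-chi^2(nu0, sigma0^2) prior on gene variances; ``tau0`` is the
    prior spread of group means, in units of the gene standard deviation under
    the default conjugate mean prior."""

    mu0: float
    tau0: float
    nu0: float
    sigma0: float
    pi: float

    def __post_init__(self) -> None:
        _check_positive(tau0=self.tau0, nu0=self.nu0, sigma0=self.sigma0)
        if not np.isfinite(self.mu0):
            raise ValueError(f"mu0 must be finite, got {self.mu0}")
        _check_pi(self.pi)

    def with_pi(self, pi: float) -> "NNHyperParams":
        return replace(self, pi=pi)


HyperParams = Union[GaGaHyperParams, NNHyperParams]


def hyper_for_model(hyper: HyperParams, model_id: str) -> HyperParams:
    """Validate that ``hyper`` matches ``model_id`` ('gaga' or 'nn')."""
    expected = {"gaga": GaGaHyperParams, "nn": NNHyperParams}
    if model_id not in expected:
        raise ValueError(f"unknown model_id {model_id!r}; expected 'gaga' or 'nn'")
    if not isinstance(hyper, expected[model_id]):
        raise TypeError(
            f"model {model_id!r} requires {expected[model_id].__name__}, "
            f"got {type(hyper).__name__}"
        )
    return hyper


@dataclass(frozen=True)
class GeneParams:
    """True per-gene parameters of a synthetic dataset (array-of-genes layout).

    ``group_means[i]`` holds (lambda_i0, lambda_i1) for GaGa or (mu_i0, mu_i1)
    for NN; equality of the two entries is enforced whenever ``delta[i] == 0``.
    ``shape_or_var`` is alpha_i (GaGa) or sigma_i^2 (NN).
    """

    delta: np.ndarray
    group_means: np.ndarray
    shape_or_var: np.ndarray

    def __post_init__(self) -> None:
        delta = np.asarray(self.delta, dtype=int)
        gm = np.asarray(self.group_means, dtype=float)
        sv = np.asarray(self.shape_or_var, dtype=float)
        n = delta.shape[0]
        if gm.shape != (n, 2) or sv.shape != (n,):
            raise ValueError("inconsistent per-gene parameter shapes")
        if not np.all(np.isin(delta, [0, 1])):
            raise ValueError("delta must be 0/1")
        ee = delta == 0
        if not np.allclose(gm[ee, 0], gm[ee, 1]):
            raise ValueError("EE genes must have equal group means")
        if np.any(sv <= 0):
            raise ValueError("shape_or_var must be strictly positive")
        object.__setattr__(self, "delta", delta)
        object.__setattr__(self, "group_means", gm)
        object.__setattr__(self, "shape_or_var", sv)

    @property
    def n_genes(self) -> int:
        return self.delta.shape[0]


@dataclass(frozen=True)
class SyntheticDataset:
    """A simulated expression batch together with its generating truth."""

    batch: "ExpressionBatch"  # noqa: F821 - forward ref, avoids import cycle
    truth: GeneParams
    generating_hyper: HyperParams

    def __post_init__(self) -> None:
        if self.truth.n_genes != self.batch.n_genes:
            raise ValueError("truth must have one entry per gene of batch")
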