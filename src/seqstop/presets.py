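"""Canonical synthetic study conditions.

These presets define the default generative settings used by the simulation
studies and examples: microarray-scale log-normal and gamma expression with a
small DE fraction, batches of two arrays per group and a ten-batch horizon.
Values are fixed package-wide so that studies and tests describe the same
synthetic population; rationale for each choice is in docs/methods.md.
"""

from __future__ import annotations

import numpy as np

from .decisions import UtilityParams
from .models import GaGaHyperParams, NNHyperParams
from .sequential import DesignSpec
from .study import ScenarioSpec

__all__ = [
    "default_nn_hyper",
    "default_gaga_hyper",
    "default_design",
    "default_util",
    "adaptation_scenario",
]


def default_nn_hyper(pi: float = 0.05) -> NNHyperParams:
    """Microarray-scale log-normal population: log-intensities centred at 7
    with gene variances around 0.45 (nu0 = 6, sigma0^2 = 0.3) and group-mean
    spread tau0 = 1.2 gene standard deviations."""
    return NNHyperParams(mu0=7.0, tau0=1.2, nu0=6.0, sigma0=float(np.sqrt(0.3)), pi=pi)


def default_gaga_hyper(pi: float = 0.063) -> GaGaHyperParams:
    """Gamma expression population: raw intensities around 1/nu = 200 with
    gene shapes averaging mu = 8 (moderately skewed measurements)."""
    return GaGaHyperParams(alpha0=2.0, nu=0.005, beta=2.0, mu=8.0, pi=pi)


def default_design(T: int = 10, per_group: int = 2, t0: int = 0) -> DesignSpec:
    """Batches of two samples per group, horizon of ten batches."""
    return DesignSpec(T=T, batch_composition=(per_group, per_group), t0=t0)


def default_util(c: float = 50.0) -> UtilityParams:
    return UtilityParams(c=c, fdr_level=0.05)


def adaptation_scenario(
    pi_scale: float,
    *,
    n_genes: int = 1000,
    nrep: int = 50,
    c: float = 50.0,
    seed: int = 0,
) -> ScenarioSpec:
    """Misspecified-DE-fraction stress scenario at desk scale.

    The analysis prior fixes pi = 0.3 while the generating pi is scaled by
    ``pi_scale`` (0.5 = overstated prior, 2 = understated).  Effects are
    moderately strong (tau0 = 1.5) and monitoring starts after one burn-in
    batch, so that the per-batch expected TP gain is comparable to the
    sampling cost and the stop/continue decision is informative — the regime
    in which a sequential design can adapt.  See docs/methods.md.
    """
    analysis = NNHyperParams(
        mu0=7.0, tau0=1.5, nu0=6.0, sigma0=float(np.sqrt(0.3)), pi=0.3
    )
    generating = analysis.with_pi(min(1.0, 0.3 * pi_scale))
    return ScenarioSpec(
        generating_hyper=generating,
        analysis_hyper=analysis,
        design=DesignSpec(T=10, batch_composition=(2, 2), t0=1),
        util=UtilityParams(c=c, fdr_level=0.05),
        n_genes=n_genes,
        nrep=nrep,
        seed=seed,
        monitor_draws=20,
    )
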