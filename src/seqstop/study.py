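"""Design evaluation over repeated simulated studies (operating characteristics).

A scenario pairs a *generating* hyperparameter vector (the truth used to
simulate data, possibly with a DE fraction pi that differs from the analyst's
prior — the classic misspecification stress test) with an *analysis*
hyperparameter vector held fixed during monitoring.  Each replication streams
data batch by batch through the live monitoring rule until it stops, then
scores the terminal decision against the known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._rng import as_rng
from .batch import ExpressionBatch
from .decisions import UtilityParams
from .models import (
    HyperParams,
    hyper_for_model,
    sample_from_prior,
    sample_posterior_predictive,
)
from .sequential import Boundary, DesignSpec, MonitorRecord, forward_simulate, monitor_step

__all__ = [
    "ScenarioSpec",
    "OperatingCharacteristics",
    "FixedDesignCurve",
    "simulate_sequential_study",
    "optimal_fixed_sample_size",
    "compare_designs",
    "posterior_predictive_check",
]


@dataclass(frozen=True)
class ScenarioSpec:
    """One simulation scenario: truth, analysis prior, design, cost, size."""

    generating_hyper: HyperParams
    analysis_hyper: HyperParams
    design: DesignSpec
    util: UtilityParams
    n_genes: int
    nrep: int = 250
    seed: int | None = None
    monitor_draws: int = 20  # inner MC draws per live stopping decision

    def __post_init__(self) -> None:
        if self.nrep < 1:
            raise ValueError("nrep must be >= 1")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")


@dataclass(frozen=True)
class OperatingCharacteristics:
    """Aggregated stopping-time / utility / FDR behaviour of a design."""

    mean_tau: float
    mean_utility: float
    mean_expected_tp: float
    mean_realized_fdr: float
    se_tau: float
    se_utility: float
    se_realized_fdr: float
    records: pd.DataFrame

    def __post_init__(self) -> None:
        if not 0.0 <= self.mean_realized_fdr <= 1.0:
            raise ValueError("mean realized FDR must lie in [0, 1]")


@dataclass(frozen=True)
class FixedDesignCurve:
    """Expected utility of deterministic stopping at each n = 0..T."""

    n_star: int
    n_values: np.ndarray
    utility: np.ndarray
    se: np.ndarray


def _mean_se(x: np.ndarray) -> tuple[float, float]:
    x = np.asarray(x, dtype=float)
    se = float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0
    return float(x.mean()), se


def _rep_seeds(seed: int | None, nrep: int) -> np.ndarray:
    return as_rng(seed).integers(0, 2**31 - 1, size=nrep)


def _run_one_replication(
    scenario: ScenarioSpec,
    boundary: Boundary,
    model_id: str,
    rep_seed: int,
) -> dict[str, float]:
    """Stream one simulated study through the monitoring rule."""
    design, util = scenario.design, scenario.util
    data_rng = np.random.default_rng([int(rep_seed), 0])
    monitor_rng = np.random.default_rng([int(rep_seed), 1])
    dataset = sample_from_prior(
        scenario.generating_hyper,
        model_id,
        scenario.n_genes,
        design.batch_composition,
        data_rng,
        n_batches=design.T,
    )
    full = dataset.batch
    t = design.t0
    rec: MonitorRecord
    while True:
        current = full.up_to_batch(t)
        rec = monitor_step(
            current,
            scenario.analysis_hyper,
            model_id,
            boundary,
            util,
            design,
            scenario.monitor_draws,
            monitor_rng,
        )
        if rec.decision == "stop":
            break
        t += 1
    tau = t
    d = rec.summary.d
    delta_true = dataset.truth.delta
    tp = float(np.sum(delta_true * d))
    D = int(d.sum())
    fdr = float(np.sum((1 - delta_true) * d) / D) if D > 0 else 0.0
    return {
        "tau": tau,
        "D": D,
        "realized_tp": tp,
        "realized_fdr": fdr,
        "realized_utility": tp - util.c * tau,
        "expected_tp": rec.summary.expected_tp,
        "posterior_fdr": rec.summary.posterior_fdr,
        "rule": rec.rule,
    }


def _aggregate(records: pd.DataFrame) -> OperatingCharacteristics:
    mean_tau, se_tau = _mean_se(records["tau"].to_numpy())
    mean_u, se_u = _mean_se(records["realized_utility"].to_numpy())
    mean_etp, _ = _mean_se(records["expected_tp"].to_numpy())
    mean_fdr, se_fdr = _mean_se(records["realized_fdr"].to_numpy())
    return OperatingCharacteristics(
        mean_tau=mean_tau,
        mean_utility=mean_u,
        mean_expected_tp=mean_etp,
        mean_realized_fdr=mean_fdr,
        se_tau=se_tau,
        se_utility=se_u,
        se_realized_fdr=se_fdr,
        records=records,
    )


def simulate_sequential_study(
    scenario: ScenarioSpec, boundary: Boundary, model_id: str
) -> OperatingCharacteristics:
    """Operating characteristics of a boundary over ``scenario.nrep`` studies.

    Per replication: simulate the truth and a full data stream from the
    generating hyperparameters, run the live monitoring rule batch by batch
    under the analysis hyperparameters until it stops, and score stopping
    time, realized TP/FDR and realized utility against the known truth.
    Deterministic given ``scenario.seed``.
    """
    hyper_for_model(scenario.generating_hyper, model_id)
    hyper_for_model(scenario.analysis_hyper, model_id)
    rows = [
        _run_one_replication(scenario, boundary, model_id, s)
        for s in _rep_seeds(scenario.seed, scenario.nrep)
    ]
    return _aggregate(pd.DataFrame(rows))


def optimal_fixed_sample_size(
    hyper: HyperParams,
    model_id: str,
    design: DesignSpec,
    util: UtilityParams,
    B: int = 500,
    rng_seed: int | np.random.Generator | None = None,
    *,
    n_genes: int = 1000,
    batch: ExpressionBatch | None = None,
) -> FixedDesignCurve:
    """Prior- (or posterior-) predictive utility of every fixed sample size.

    Simulates B complete data trajectories (from the prior predictive when no
    ``batch`` is given) and, for each n in {t0..T}, averages expected TP after
    n batches minus c * n.  Ties at the maximum resolve to the smallest n.
    """
    if batch is None:
        gene_ids = np.array([f"g{i:05d}" for i in range(n_genes)])
        batch = ExpressionBatch.empty(gene_ids)
        design = replace(design, t0=0)
    trajset = forward_simulate(batch, hyper, model_id, design, util, B, rng_seed)
    n_values = np.arange(design.t0, design.T + 1)
    utility = trajset.expected_tp_at.mean(axis=0) - util.c * n_values
    se = trajset.expected_tp_at.std(axis=0, ddof=1) / np.sqrt(trajset.B)
    n_star = int(n_values[int(np.argmax(utility))])
    return FixedDesignCurve(n_star=n_star, n_values=n_values, utility=utility, se=se)


def compare_designs(
    scenario: ScenarioSpec,
    boundary: Boundary,
    fixed_n: int,
    model_id: str,
) -> pd.DataFrame:
    """Paired comparison of a sequential boundary against a fixed-n design.

    Both designs see identical simulated data streams and identical inner
    Monte Carlo draws (shared per-replication seeds), so the reported
    differences are purely due to the stopping rules.  The fixed design is
    encoded as its boundary special case: b0 = -inf with horizon ``fixed_n``.
    """
    if not scenario.design.t0 <= fixed_n <= scenario.design.T:
        raise ValueError("fixed_n must lie within the design's batch range")
    fixed_design = replace(scenario.design, T=fixed_n) if fixed_n > scenario.design.t0 else None
    if fixed_design is None:
        raise ValueError("fixed_n must exceed t0 for a meaningful fixed design")
    fixed_scenario = replace(scenario, design=fixed_design)
    fixed_boundary = Boundary(-np.inf, 0.0)
    rows = []
    for s in _rep_seeds(scenario.seed, scenario.nrep):
        seq = _run_one_replication(scenario, boundary, model_id, s)
        fix = _run_one_replication(fixed_scenario, fixed_boundary, model_id, s)
        rows.append(
            {
                "tau_seq": seq["tau"],
                "tau_fixed": fix["tau"],
                "utility_seq": seq["realized_utility"],
                "utility_fixed": fix["realized_utility"],
                "diff_utility": seq["realized_utility"] - fix["realized_utility"],
                "diff_tau": seq["tau"] - fix["tau"],
            }
        )
    return pd.DataFrame(rows)


def posterior_predictive_check(
    batch: ExpressionBatch,
    hyper: HyperParams,
    model_id: str,
    rng_seed: int | np.random.Generator | None = None,
    *,
    n_rep: int = 50,
    quantiles: tuple[float, ...] = (0.1, 0.25, 0.5, 0.75, 0.9),
) -> pd.DataFrame:
    """Posterior-predictive quantile check of gene-level moments.

    Compares observed cross-gene quantiles of the per-gene mean, variance and
    skewness (computed on the log scale for both models) with their
    distribution over replicate datasets simulated from the fitted model.
    Rows flagged ``outside`` fall beyond the central 95% simulation band.
    """
    if batch.n_samples == 0:
        raise ValueError("posterior predictive check needs observed data")
    rng = as_rng(rng_seed)
    k0, k1 = batch.samples_per_group()

    def gene_stats(values: np.ndarray) -> dict[str, np.ndarray]:
        y = np.log(values)
        return {
            "mean": y.mean(axis=1),
            "variance": y.var(axis=1, ddof=1) if y.shape[1] > 1 else y.var(axis=1),
            "skewness": sps.skew(y, axis=1),
        }

    observed = gene_stats(batch.values)
    qs = np.asarray(quantiles)
    sims: dict[str, list[np.ndarray]] = {k: [] for k in observed}
    for child in rng.spawn(n_rep):
        draw = sample_posterior_predictive(batch, hyper, model_id, (k0, k1), child)
        rep_stats = gene_stats(draw.values)
        for k in sims:
            sims[k].append(np.quantile(rep_stats[k], qs))
    rows = []
    for stat, obs in observed.items():
        obs_q = np.quantile(obs, qs)
        sim_q = np.vstack(sims[stat])  # (n_rep, len(qs))
        lo, hi = np.quantile(sim_q, [0.025, 0.975], axis=0)
        for i, q in enumerate(qs):
            rows.append(
                {
                    "statistic": stat,
                    "quantile": q,
                    "observed": obs_q[i],
                    "sim_mean": sim_q[:, i].mean(),
                    "sim_lo": lo[i],
                    "sim_hi": hi[i],
                    "outside": bool(obs_q[i] < lo[i] or obs_q[i] > hi[i]),
                }
            )
    return pd.DataFrame(rows)
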