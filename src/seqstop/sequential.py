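"""Forward simulation, linear stopping boundaries and their optimisation.

The monitoring statistic is the one-step-ahead expected gain in true
positives, Delta_t(TP): the expected increase in sum_i d_i v_i if one more
batch were observed.  Since the utility gain of one more batch is
Delta_t U = Delta_t(TP) - c, boundaries are expressed on the Delta_t(TP)
scale.  A linear boundary b = (b0, b1) stops at the first monitoring time
k with Delta_k(TP) <= b0 + b1 * k; strictly above means continue.  At the
last monitoring time T-1 the boundary is replaced by the myopic rule
(continue iff Delta_{T-1} U > 0) and at the horizon T stopping is forced.

Two familiar designs are special cases: b = (c, 0) is the myopic rule, and
b0 = -inf (never stop early) with horizon T' is the fixed-sample design with
T' batches.

Boundaries are evaluated by forward simulation: B complete future data
trajectories are drawn from the posterior predictive, each recording the
realized one-step increments Delta_k(TP); a boundary's expected utility is
the trajectory average of expected-TP-at-stopping minus c * stopping time,
and the optimal boundary is found by grid search.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import as_rng
from .batch import ExpressionBatch
from .decisions import PosteriorSummary, UtilityParams, bayes_terminal_decision
from .models import HyperParams, posterior_de_prob, sample_posterior_predictive

__all__ = [
    "DesignSpec",
    "Boundary",
    "TrajectorySet",
    "StoppingRecord",
    "DeltaTPEstimate",
    "BoundaryUtility",
    "BoundaryOptimum",
    "MonitorRecord",
    "delta_tp_onestep",
    "forward_simulate",
    "stopping_time",
    "apply_boundary",
    "boundary_expected_utility",
    "optimize_boundary",
    "default_grid",
    "monitor_step",
]


@dataclass(frozen=True)
class DesignSpec:
    """Batch-accrual design: horizon, batch composition, batches in hand."""

    T: int
    batch_composition: tuple[int, int] = (2, 2)
    t0: int = 0

    def __post_init__(self) -> None:
        if self.T < 1:
            raise ValueError(f"horizon T must be >= 1, got {self.T}")
        k0, k1 = self.batch_composition
        if k0 < 0 or k1 < 0 or max(k0, k1) < 1:
            raise ValueError("batch_composition needs >= 1 sample in some group")
        if not 0 <= self.t0 < self.T:
            raise ValueError(f"t0 must satisfy 0 <= t0 < T, got t0={self.t0}, T={self.T}")


@dataclass(frozen=True)
class Boundary:
    """Linear stopping boundary on the Delta_t(TP) scale.

    ``b0 = -inf`` is the sentinel for "never stop before the horizon".
    """

    b0: float
    b1: float = 0.0

    def __post_init__(self) -> None:
        if np.isnan(self.b0) or not np.isfinite(self.b1):
            raise ValueError("b1 must be finite and b0 finite or -inf")
        if self.b0 == np.inf:
            raise ValueError("b0 = +inf (stop always) is not a meaningful boundary")

    def threshold(self, k: int | np.ndarray) -> float | np.ndarray:
        return self.b0 + self.b1 * k


@dataclass(frozen=True)
class TrajectorySet:
    """B simulated futures: per-step Delta_k(TP) and expected-TP levels.

    ``delta_tp[j, i]`` is the realized one-step increment recorded at
    monitoring time ``k = t0 + i`` (i.e. expected TP after batch ``k+1``
    minus after batch ``k``), for ``k = t0 .. T-1``.  ``expected_tp_at[j, i]``
    is the expected TP after ``t0 + i`` batches, ``i = 0 .. T - t0`` (column 0
    is the common value on the observed data).
    """

    delta_tp: np.ndarray
    expected_tp_at: np.ndarray
    t0: int
    T: int
    seed_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        b, k = self.delta_tp.shape
        if k != self.T - self.t0 or self.expected_tp_at.shape != (b, k + 1):
            raise ValueError("inconsistent trajectory dimensions")
        if not (np.all(np.isfinite(self.delta_tp)) and np.all(np.isfinite(self.expected_tp_at))):
            raise ValueError("trajectory entries must be finite")

    @property
    def B(self) -> int:
        return self.delta_tp.shape[0]

    def steps(self) -> np.ndarray:
        """Monitoring times k = t0 .. T-1 matching delta_tp columns."""
        return np.arange(self.t0, self.T)

    def to_frame(self) -> pd.DataFrame:
        """Long-format export: one row per trajectory and monitoring step."""
        B, K = self.delta_tp.shape
        return pd.DataFrame(
            {
                "trajectory": np.repeat(np.arange(B), K),
                "step": np.tile(self.steps(), B),
                "delta_tp": self.delta_tp.ravel(),
                "expected_tp_after": self.expected_tp_at[:, 1:].ravel(),
            }
        )


@dataclass(frozen=True)
class StoppingRecord:
    """Per-trajectory stopping times, realized utilities and the rule used."""

    tau: np.ndarray
    utility: np.ndarray
    rule_applied: np.ndarray  # {"boundary", "horizon_myopic", "horizon_forced"}


@dataclass(frozen=True)
class DeltaTPEstimate:
    estimate: float
    se: float
    m: int


@dataclass(frozen=True)
class BoundaryUtility:
    utility: float
    se: float
    mean_tau: float
    record: StoppingRecord


@dataclass(frozen=True)
class BoundaryOptimum:
    """Grid-search result: representative optimum, near-optimal set, surface."""

    best: Boundary
    best_utility: float
    best_se: float
    optima: tuple[Boundary, ...]
    surface: pd.DataFrame


@dataclass(frozen=True)
class MonitorRecord:
    decision: str  # "continue" | "stop"
    t: int
    delta_tp: float
    se: float
    threshold: float
    rule: str
    summary: PosteriorSummary


# ---------------------------------------------------------------------------


def _summary_now(
    batch: ExpressionBatch, hyper: HyperParams, model_id: str, util: UtilityParams,
    n_nodes: int,
) -> PosteriorSummary:
    v = posterior_de_prob(batch, hyper, model_id, n_nodes=n_nodes)
    return bayes_terminal_decision(v, util.fdr_level)


def delta_tp_onestep(
    batch: ExpressionBatch,
    hyper: HyperParams,
    model_id: str,
    util: UtilityParams,
    batch_composition: tuple[int, int],
    m: int = 100,
    rng_seed: int | np.random.Generator | None = None,
    *,
    n_nodes: int = 64,
) -> DeltaTPEstimate:
    """Monte Carlo estimate of Delta_t(TP) with its standard error.

    Draws ``m`` one-step-ahead batches from the posterior predictive,
    recomputes the posterior summary on each augmented dataset and averages
    the expected-TP gains.  Independent substreams are used per draw.
    """
    if m < 1:
        raise ValueError("need at least one Monte Carlo draw")
    rng = as_rng(rng_seed)
    now = _summary_now(batch, hyper, model_id, util, n_nodes)
    gains = np.empty(m)
    for i, child in enumerate(rng.spawn(m)):
        draw = sample_posterior_predictive(
            batch, hyper, model_id, batch_composition, child, n_nodes=n_nodes
        )
        augmented = batch.extend(draw.values, draw.groups)
        after = _summary_now(augmented, hyper, model_id, util, n_nodes)
        gains[i] = after.expected_tp - now.expected_tp
    se = float(gains.std(ddof=1) / np.sqrt(m)) if m > 1 else 0.0
    return DeltaTPEstimate(estimate=float(gains.mean()), se=se, m=m)


def forward_simulate(
    batch: ExpressionBatch,
    hyper: HyperParams,
    model_id: str,
    design: DesignSpec,
    util: UtilityParams,
    B: int = 500,
    rng_seed: int | np.random.Generator | None = None,
    *,
    n_nodes: int = 64,
    max_cells: float = 5e8,
) -> TrajectorySet:
    """Simulate B complete futures x_{t0+1 : T} from the posterior predictive.

    Along each trajectory the posterior summary is recomputed on the
    accumulated (real + simulated) data after every batch, and the realized
    one-step increment Delta_k(TP) is recorded.  Trajectories use independent
    child streams of the root seed.
    """
    if B < 1:
        raise ValueError("need at least one trajectory")
    if batch.t != design.t0:
        raise ValueError(f"batch holds {batch.t} batches but design.t0 = {design.t0}")
    if design.t0 >= design.T:
        raise ValueError("horizon already reached")
    if batch.n_genes * B * design.T > max_cells:
        raise ValueError(
            f"forward simulation would touch > {max_cells:.0g} gene-level cells; "
            "reduce B or raise max_cells"
        )
    rng = as_rng(rng_seed)
    now = _summary_now(batch, hyper, model_id, util, n_nodes)
    K = design.T - design.t0
    delta = np.empty((B, K))
    etp = np.empty((B, K + 1))
    etp[:, 0] = now.expected_tp
    for j, child in enumerate(rng.spawn(B)):
        current = batch
        prev_tp = now.expected_tp
        for i in range(K):
            draw = sample_posterior_predictive(
                current, hyper, model_id, design.batch_composition, child,
                n_nodes=n_nodes,
            )
            current = current.extend(draw.values, draw.groups)
            summary = _summary_now(current, hyper, model_id, util, n_nodes)
            delta[j, i] = summary.expected_tp - prev_tp
            etp[j, i + 1] = summary.expected_tp
            prev_tp = summary.expected_tp
    return TrajectorySet(
        delta_tp=delta, expected_tp_at=etp, t0=design.t0, T=design.T,
        seed_meta={"B": B},
    )


def stopping_time(
    trajectory: np.ndarray,
    boundary: Boundary,
    util: UtilityParams,
    design: DesignSpec,
) -> tuple[int, str]:
    """Stopping time of one Delta_k(TP) path under a linear boundary.

    The path must cover monitoring times ``t0 .. T-1``.  Stop at the first
    k <= T-2 with Delta_k(TP) <= b0 + b1 * k; otherwise apply the myopic rule
    at T-1 (stop iff Delta_{T-1}(TP) - c <= 0); otherwise run to the horizon.
    """
    trajectory = np.asarray(trajectory, dtype=float)
    K = design.T - design.t0
    if trajectory.shape != (K,):
        raise ValueError(
            f"trajectory must cover steps {design.t0}..{design.T - 1} "
            f"({K} values), got shape {trajectory.shape}"
        )
    for i, k in enumerate(range(design.t0, design.T - 1)):
        if trajectory[i] <= boundary.threshold(k):
            return k, "boundary"
    if trajectory[K - 1] - util.c <= 0:
        return design.T - 1, "horizon_myopic"
    return design.T, "horizon_forced"


def apply_boundary(
    trajset: TrajectorySet, boundary: Boundary, util: UtilityParams
) -> StoppingRecord:
    """Vectorised stopping times and realized utilities for all trajectories."""
    K = trajset.T - trajset.t0
    ks = trajset.steps()[: K - 1]
    delta = trajset.delta_tp
    if K > 1:
        below = delta[:, : K - 1] <= boundary.threshold(ks)[None, :]
    else:
        below = np.zeros((trajset.B, 0), dtype=bool)
    any_below = below.any(axis=1)
    first = np.argmax(below, axis=1)
    tau = np.where(any_below, trajset.t0 + first, 0)
    myopic_stop = delta[:, K - 1] - util.c <= 0
    tau = np.where(
        any_below, tau, np.where(myopic_stop, trajset.T - 1, trajset.T)
    )
    rule = np.where(
        any_below, "boundary", np.where(myopic_stop, "horizon_myopic", "horizon_forced")
    )
    etp_at_tau = trajset.expected_tp_at[np.arange(trajset.B), tau - trajset.t0]
    utility = etp_at_tau - util.c * tau
    return StoppingRecord(tau=tau, utility=utility, rule_applied=rule)


def boundary_expected_utility(
    trajset: TrajectorySet, boundary: Boundary, util: UtilityParams
) -> BoundaryUtility:
    """Monte Carlo expected utility U(b, x_{1:t}) of a boundary."""
    if trajset.B < 1:
        raise ValueError("empty trajectory set")
    record = apply_boundary(trajset, boundary, util)
    u = record.utility
    se = float(u.std(ddof=1) / np.sqrt(len(u))) if len(u) > 1 else 0.0
    return BoundaryUtility(
        utility=float(u.mean()), se=se, mean_tau=float(record.tau.mean()), record=record
    )


def default_grid(util: UtilityParams, n_b0: int = 21, n_b1: int = 21):
    """Default search grid: b0 in [0, 3c], b1 in [-c, c]."""
    c = max(util.c, 1.0)
    return np.linspace(0.0, 3.0 * c, n_b0), np.linspace(-c, c, n_b1)


def optimize_boundary(
    trajset: TrajectorySet,
    grid: tuple[np.ndarray, np.ndarray] | None,
    util: UtilityParams,
) -> BoundaryOptimum:
    """Grid search for the boundary maximising the forward-simulated utility.

    Returns every boundary within one MC standard error of the maximum (the
    near-optimal set), a representative chosen as the member with the smallest
    expected stopping time (cheapest among equals), and the full utility
    surface for diagnostics.
    """
    if trajset.B < 1:
        raise ValueError("empty trajectory set")
    b0s, b1s = grid if grid is not None else default_grid(util)
    b0s, b1s = np.atleast_1d(b0s), np.atleast_1d(b1s)
    if b0s.size == 0 or b1s.size == 0:
        raise ValueError("empty boundary grid")
    rows = []
    for b0 in b0s:
        for b1 in b1s:
            bu = boundary_expected_utility(trajset, Boundary(b0, b1), util)
            rows.append((b0, b1, bu.utility, bu.se, bu.mean_tau))
    surface = pd.DataFrame(
        rows, columns=["b0", "b1", "utility", "se", "mean_tau"]
    )
    i_best = int(surface["utility"].idxmax())
    u_max = surface.loc[i_best, "utility"]
    se_max = surface.loc[i_best, "se"]
    near = surface[surface["utility"] >= u_max - se_max]
    i_rep = int(near["mean_tau"].idxmin())
    optima = tuple(Boundary(r.b0, r.b1) for r in near.itertuples())
    return BoundaryOptimum(
        best=Boundary(surface.loc[i_rep, "b0"], surface.loc[i_rep, "b1"]),
        best_utility=float(surface.loc[i_rep, "utility"]),
        best_se=float(surface.loc[i_rep, "se"]),
        optima=optima,
        surface=surface,
    )


def monitor_step(
    batch: ExpressionBatch,
    hyper: HyperParams,
    model_id: str,
    boundary: Boundary,
    util: UtilityParams,
    design: DesignSpec,
    m: int = 100,
    rng_seed: int | np.random.Generator | None = None,
    *,
    n_nodes: int = 64,
) -> MonitorRecord:
    """Live stop/continue decision after observing the data in ``batch``.

    Estimates Delta_t(TP) by inner Monte Carlo averaging and compares it with
    the boundary (or the myopic rule at T-1).  At t >= T stopping is forced.
    """
    t = batch.t
    if t >= design.T:
        summary = _summary_now(batch, hyper, model_id, util, n_nodes)
        return MonitorRecord(
            decision="stop", t=t, delta_tp=float("nan"), se=0.0,
            threshold=float("nan"), rule="horizon_forced", summary=summary,
        )
    est = delta_tp_onestep(
        batch, hyper, model_id, util, design.batch_composition, m, rng_seed,
        n_nodes=n_nodes,
    )
    if t == design.T - 1:
        threshold, rule = util.c, "horizon_myopic"
    else:
        threshold, rule = float(boundary.threshold(t)), "boundary"
    decision = "continue" if est.estimate > threshold else "stop"
    summary = _summary_now(batch, hyper, model_id, util, n_nodes)
    return MonitorRecord(
        decision=decision, t=t, delta_tp=est.estimate, se=est.se,
        threshold=threshold, rule=rule, summary=summary,
    )
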