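"""Terminal decisions and the utility calculus.

Upon stopping, genes are classified DE/EE by the Bayes rule that flags the
largest set whose posterior expected false discovery rate

    FDR_bar(d) = sum_i (1 - v_i) d_i / max(D, 1),   D = sum_i d_i

stays at or below a target level (0.05 by default): sort genes by v_i
descending and keep the longest prefix whose running mean of (1 - v_i) is
within the level.  Since (1 - v_i) is non-decreasing along that order the
running mean is non-decreasing too, so the feasible prefixes form an initial
segment; for distinct v_i the rule is the exact maximiser of D subject to the
constraint.  Ties in v_i are included or excluded as whole blocks.

The sequential utility attaches a sampling cost c per batch and a unit reward
per true positive:  u = sum_i delta_i d_i - c * t.  Its posterior expectation
given the decision d is  sum_i d_i v_i - c * t ; c is interpretable as the
minimum number of new true positives that justify one more batch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "UtilityParams",
    "PosteriorSummary",
    "bayes_terminal_decision",
    "posterior_expected_fdr",
    "expected_true_positives",
    "expected_terminal_utility",
    "decision_table",
]


@dataclass(frozen=True)
class UtilityParams:
    """Sampling cost per batch and the terminal FDR level."""

    c: float = 50.0
    fdr_level: float = 0.05

    def __post_init__(self) -> None:
        if self.c < 0:
            raise ValueError(f"sampling cost must be >= 0, got {self.c}")
        if not 0.0 < self.fdr_level <= 1.0:
            raise ValueError(f"fdr_level must lie in (0, 1], got {self.fdr_level}")


@dataclass(frozen=True)
class PosteriorSummary:
    """Per-gene posterior DE probabilities with the induced terminal decision."""

    v: np.ndarray
    d: np.ndarray
    fdr_level: float
    posterior_fdr: float
    expected_tp: float
    D: int

    def __post_init__(self) -> None:
        if self.D != int(self.d.sum()):
            raise ValueError("D must equal the number of positive decisions")
        if self.D > 0 and self.posterior_fdr > self.fdr_level + 1e-12:
            raise ValueError("posterior FDR exceeds the target level")


def _check_v(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.ndim != 1:
        raise ValueError("v must be a 1-D probability vector")
    if v.size and (np.any(v < 0) or np.any(v > 1) or not np.all(np.isfinite(v))):
        raise ValueError("posterior probabilities must lie in [0, 1]")
    return v


def _check_pair(v: np.ndarray, d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    v = _check_v(v)
    d = np.asarray(d)
    if d.shape != v.shape:
        raise ValueError(f"decision vector shape {d.shape} != v shape {v.shape}")
    if d.size and not np.all(np.isin(d, [0, 1])):
        raise ValueError("decisions must be binary")
    return v, d.astype(int)


def posterior_expected_fdr(v: np.ndarray, d: np.ndarray) -> float:
    """Posterior expected FDR of decision d; 0 by convention when D = 0."""
    v, d = _check_pair(v, d)
    D = int(d.sum())
    if D == 0:
        return 0.0
    return float(np.sum((1.0 - v) * d) / D)


def expected_true_positives(v: np.ndarray, d: np.ndarray) -> float:
    """Posterior expected number of true positives, sum_i d_i v_i."""
    v, d = _check_pair(v, d)
    return float(np.sum(v * d))


def expected_terminal_utility(
    v: np.ndarray, d: np.ndarray, util: UtilityParams, t: int
) -> float:
    """Posterior expected utility of stopping after t batches with decision d."""
    if t < 0:
        raise ValueError(f"number of batches must be >= 0, got {t}")
    return expected_true_positives(v, d) - util.c * t


def bayes_terminal_decision(v: np.ndarray, fdr_level: float = 0.05) -> PosteriorSummary:
    """Flag the largest gene set with posterior expected FDR <= fdr_level.

    Ties in v share a fate: a tied block enters only if the whole block keeps
    the constraint.  D = 0 is allowed (posterior FDR defined as 0).
    """
    if not 0.0 < fdr_level <= 1.0:
        raise ValueError(f"fdr_level must lie in (0, 1], got {fdr_level}")
    v = _check_v(v)
    n = v.size
    d = np.zeros(n, dtype=int)
    if n:
        order = np.lexsort((np.arange(n), -v))  # v desc, index asc (stable)
        vs = v[order]
        run_mean = np.cumsum(1.0 - vs) / np.arange(1, n + 1)
        feasible = run_mean <= fdr_level
        # block boundaries: positions where the next v differs (or the end)
        block_end = np.r_[vs[:-1] != vs[1:], True]
        ok = feasible & block_end
        if np.any(ok):
            D = int(np.flatnonzero(ok)[-1]) + 1
            d[order[:D]] = 1
    D = int(d.sum())
    return PosteriorSummary(
        v=v,
        d=d,
        fdr_level=fdr_level,
        posterior_fdr=posterior_expected_fdr(v, d),
        expected_tp=expected_true_positives(v, d),
        D=D,
    )


def decision_table(summary: PosteriorSummary, gene_ids) -> "pd.DataFrame":
    """Per-gene report: v, decision, rank and running posterior FDR."""
    import pandas as pd

    v = summary.v
    n = v.size
    order = np.lexsort((np.arange(n), -v))
    run_fdr = np.cumsum(1.0 - v[order]) / np.arange(1, n + 1)
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(1, n + 1)
    cum = np.empty(n)
    cum[order] = run_fdr
    return pd.DataFrame(
        {
            "gene_id": np.asarray(gene_ids),
            "v": v,
            "d": summary.d,
            "rank": rank,
            "cumulative_fdr": cum,
        }
    ).sort_values("rank", ignore_index=True)
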