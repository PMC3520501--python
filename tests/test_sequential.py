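"""Stopping rules, forward simulation, and boundary optimisation."""

import numpy as np
import pytest

from seqstop import (
    Boundary,
    DesignSpec,
    ExpressionBatch,
    TrajectorySet,
    UtilityParams,
    boundary_expected_utility,
    default_nn_hyper,
    delta_tp_onestep,
    forward_simulate,
    monitor_step,
    optimize_boundary,
    sample_from_prior,
    stopping_time,
)
from seqstop.sequential import apply_boundary

from . import oracles


def make_trajset(delta, etp_at, t0=0):
    delta = np.asarray(delta, float)
    etp_at = np.asarray(etp_at, float)
    return TrajectorySet(delta_tp=delta, expected_tp_at=etp_at, t0=t0,
                         T=t0 + delta.shape[1])


class TestStoppingTime:
    def test_myopic_boundary_stops_when_gain_drops_below_cost(self):
        util = UtilityParams(c=50.0)
        design = DesignSpec(T=5, t0=0)
        tau, rule = stopping_time([60, 40, 30, 20, 10], Boundary(50.0, 0.0), util, design)
        assert (tau, rule) == (1, "boundary")

    def test_never_stop_sentinel_runs_to_horizon(self):
        util = UtilityParams(c=5.0)
        design = DesignSpec(T=4, t0=0)
        tau, rule = stopping_time([9, 9, 9, 9], Boundary(-np.inf, 0.0), util, design)
        assert (tau, rule) == (4, "horizon_forced")
        tau, rule = stopping_time([9, 9, 9, 3], Boundary(-np.inf, 0.0), util, design)
        assert (tau, rule) == (3, "horizon_myopic")

    def test_sloped_boundary_hand_enumeration(self):
        # thresholds at k=0,1 are 0,1 -> no stop; at T-1=2: delta - c = 1 > 0
        util = UtilityParams(c=1.0)
        design = DesignSpec(T=3, t0=0)
        tau, rule = stopping_time([10, 6, 2], Boundary(0.0, 1.0), util, design)
        assert (tau, rule) == (3, "horizon_forced")

    def test_boundary_tie_stops(self):
        util = UtilityParams(c=1.0)
        design = DesignSpec(T=3, t0=0)
        tau, rule = stopping_time([5.0, 9, 9], Boundary(5.0, 0.0), util, design)
        assert (tau, rule) == (0, "boundary")

    def test_incomplete_trajectory_rejected(self):
        with pytest.raises(ValueError, match="cover"):
            stopping_time([1.0, 2.0], Boundary(0.0, 0.0), UtilityParams(c=1.0),
                          DesignSpec(T=5, t0=0))

    def test_vectorised_matches_scalar(self, rng):
        design = DesignSpec(T=6, t0=1)
        util = UtilityParams(c=2.0)
        delta = rng.normal(3, 2, size=(40, 5))
        etp = np.abs(rng.normal(10, 2, size=(40, 6)))
        ts = make_trajset(delta, etp, t0=1)
        for b in [Boundary(2.0, 0.0), Boundary(-np.inf, 0.0), Boundary(1.0, 0.5)]:
            rec = apply_boundary(ts, b, util)
            for j in range(ts.B):
                tau, rule = stopping_time(delta[j], b, util, design)
                assert rec.tau[j] == tau and rec.rule_applied[j] == rule


class TestBoundaryUtility:
    def test_hand_computed_average(self):
        # two trajectories, T=3, c=1, boundary stops path 0 at k=1
        ts = make_trajset([[5, 0.5, 4], [5, 4, 3]], [[0, 5, 5.5, 9.5], [0, 5, 9, 12]])
        util = UtilityParams(c=1.0)
        bu = boundary_expected_utility(ts, Boundary(1.0, 0.0), util)
        # path 0: tau=1, etp=5, u=4 ; path 1: no boundary stop, delta_2-c=2>0 -> tau=3, u=9
        assert bu.utility == pytest.approx((4 + 9) / 2)
        assert bu.mean_tau == pytest.approx(2.0)

    def test_all_stop_immediately_zero_variance(self):
        ts = make_trajset([[0.0, 0.0], [0.0, 0.0]], [[7, 7, 7], [7, 7, 7]])
        util = UtilityParams(c=1.0)
        bu = boundary_expected_utility(ts, Boundary(3.0, 0.0), util)
        assert bu.utility == pytest.approx(7.0)
        assert bu.se == 0.0

    def test_non_increasing_in_cost(self, rng):
        ts = make_trajset(rng.normal(5, 2, (30, 4)), np.abs(rng.normal(20, 3, (30, 5))))
        prev = np.inf
        for c in [0.0, 1.0, 3.0, 10.0]:
            u = boundary_expected_utility(ts, Boundary(2.0, 0.0), UtilityParams(c=c)).utility
            assert u <= prev + 1e-12
            prev = u

    def test_invariant_to_trajectory_order(self, rng):
        delta = rng.normal(4, 2, (25, 4))
        etp = np.abs(rng.normal(15, 3, (25, 5)))
        perm = rng.permutation(25)
        util = UtilityParams(c=2.0)
        a = boundary_expected_utility(make_trajset(delta, etp), Boundary(3.0, 0.2), util)
        b = boundary_expected_utility(
            make_trajset(delta[perm], etp[perm]), Boundary(3.0, 0.2), util
        )
        assert a.utility == pytest.approx(b.utility)


class TestOptimizeBoundary:
    def test_single_point_grid_returns_it(self, rng):
        ts = make_trajset(rng.normal(3, 1, (10, 3)), np.abs(rng.normal(9, 2, (10, 4))))
        util = UtilityParams(c=1.0)
        opt = optimize_boundary(ts, (np.array([2.0]), np.array([0.5])), util)
        assert (opt.best.b0, opt.best.b1) == (2.0, 0.5)
        assert opt.best_utility == pytest.approx(
            boundary_expected_utility(ts, Boundary(2.0, 0.5), util).utility
        )

    def test_optimum_dominates_myopic_point(self, rng):
        ts = make_trajset(rng.normal(3, 2, (50, 5)), np.abs(rng.normal(12, 3, (50, 6))))
        util = UtilityParams(c=3.0)
        grid = (np.array([0.0, 1.5, 3.0, 6.0]), np.array([-1.0, 0.0, 1.0]))
        opt = optimize_boundary(ts, grid, util)
        u_surface_max = opt.surface["utility"].max()
        u_myopic = boundary_expected_utility(ts, Boundary(util.c, 0.0), util).utility
        assert u_surface_max >= u_myopic - 1e-12

    def test_matches_brute_force_on_small_instance(self, rng):
        delta = rng.normal(2, 2, (5, 3))
        etp = np.abs(rng.normal(8, 2, (5, 4)))
        ts = make_trajset(delta, etp)
        util = UtilityParams(c=1.5)
        b0s, b1s = np.linspace(0, 4, 5), np.linspace(-1, 1, 5)
        opt = optimize_boundary(ts, (b0s, b1s), util)
        ref = oracles.boundary_utilities(
            delta, etp, 0, 3, util.c, [(a, b) for a in b0s for b in b1s]
        )
        for row in opt.surface.itertuples():
            assert row.utility == pytest.approx(ref[(row.b0, row.b1)], abs=1e-10)
        best_ref = max(ref.values())
        assert opt.surface["utility"].max() == pytest.approx(best_ref, abs=1e-10)

    def test_empty_grid_rejected(self, rng):
        ts = make_trajset(rng.normal(2, 1, (3, 2)), np.abs(rng.normal(5, 1, (3, 3))))
        with pytest.raises(ValueError, match="grid"):
            optimize_boundary(ts, (np.array([]), np.array([0.0])), UtilityParams(c=1))


@pytest.fixture(scope="module")
def nn_pilot():
    hyper = default_nn_hyper(pi=0.2)
    batch = sample_from_prior(hyper, "nn", 150, (3, 3), 31).batch
    return hyper, batch


class TestDeltaTpOnestep:
    def test_zero_prior_gives_exactly_zero(self, nn_pilot):
        hyper, batch = nn_pilot
        est = delta_tp_onestep(
            batch, hyper.with_pi(0.0), "nn", UtilityParams(c=1.0), (2, 2), m=5,
            rng_seed=1,
        )
        assert est.estimate == 0.0 and est.se == 0.0

    def test_reproducible_given_seed(self, nn_pilot):
        hyper, batch = nn_pilot
        util = UtilityParams(c=1.0)
        a = delta_tp_onestep(batch, hyper, "nn", util, (2, 2), m=10, rng_seed=4)
        b = delta_tp_onestep(batch, hyper, "nn", util, (2, 2), m=10, rng_seed=4)
        assert a.estimate == b.estimate and a.se == b.se

    def test_two_gene_toy_matches_grid_integration(self):
        """Exhaustive fine-grid integration over the one-step predictive for
        a 2-gene, 1-sample-per-group step."""
        from seqstop import posterior_de_prob
        from seqstop.models.lnn import log_marginal_patterns

        hyper = default_nn_hyper(pi=0.3)
        util = UtilityParams(c=1.0, fdr_level=0.3)
        rng = np.random.default_rng(17)
        values = np.exp(rng.normal(7, 1, (2, 6)))
        groups = np.array([0, 0, 0, 1, 1, 1])
        batch = ExpressionBatch(values=values, groups=groups,
                                batch_index=np.ones(6, int), gene_ids=["a", "b"])
        est = delta_tp_onestep(batch, hyper, "nn", util, (1, 1), m=5000, rng_seed=9)

        # oracle: per-gene grid over the two new log-values, then the exact
        # expectation of the decision functional over the product grid
        def gene_grid(i):
            x0, x1 = values[i, :3], values[i, 3:]
            grid = np.linspace(3.0, 11.0, 161)  # log scale, covers the mass
            step = grid[1] - grid[0]
            vv = np.empty((grid.size, grid.size))
            ww = np.empty_like(vv)
            ee0, de0 = log_marginal_patterns(
                x0.reshape(1, -1), x1.reshape(1, -1), hyper
            )
            for a_idx, ya in enumerate(grid):
                xa = np.exp(ya)
                x0n = np.append(x0, xa).reshape(1, -1)
                for b_idx, yb in enumerate(grid):
                    xb = np.exp(yb)
                    x1n = np.append(x1, xb).reshape(1, -1)
                    ee, de = log_marginal_patterns(x0n, x1n, hyper)
                    num = hyper.pi * np.exp(de[0])
                    den = num + (1 - hyper.pi) * np.exp(ee[0])
                    vv[a_idx, b_idx] = num / den
                    # predictive density of (ya, yb): mixture marginal ratio
                    # (log-scale densities, so no x Jacobian)
                    ww[a_idx, b_idx] = den / (
                        hyper.pi * np.exp(de0[0]) + (1 - hyper.pi) * np.exp(ee0[0])
                    )
            ww *= step**2
            return vv.ravel(), ww.ravel() / ww.sum()

        v1, w1 = gene_grid(0)
        v2, w2 = gene_grid(1)
        exp_after = 0.0
        for start in range(0, v1.size, 512):  # chunked outer product
            va = v1[start : start + 512][:, None]
            wa = w1[start : start + 512][:, None]
            hi = np.maximum(va, v2[None, :])
            take_hi = (1 - hi) <= util.fdr_level
            take_both = (2 - va - v2[None, :]) / 2 <= util.fdr_level
            etp = np.where(take_both, va + v2[None, :], np.where(take_hi, hi, 0.0))
            exp_after += float((wa * w2[None, :] * etp).sum())
        v_now = posterior_de_prob(batch, hyper, "nn")
        hi_n = max(v_now)
        if (2 - v_now.sum()) / 2 <= util.fdr_level:
            etp_now = v_now.sum()
        elif 1 - hi_n <= util.fdr_level:
            etp_now = hi_n
        else:
            etp_now = 0.0
        oracle = exp_after - etp_now
        assert est.estimate == pytest.approx(oracle, abs=3 * max(est.se, 1e-4))


class TestForwardSimulate:
    def test_single_trajectory_matches_onestep_with_shared_stream(self, nn_pilot):
        hyper, batch = nn_pilot
        util = UtilityParams(c=1.0)
        design = DesignSpec(T=2, batch_composition=(2, 2), t0=1)
        ts = forward_simulate(batch, hyper, "nn", design, util, B=1, rng_seed=55)
        est = delta_tp_onestep(batch, hyper, "nn", util, (2, 2), m=1, rng_seed=55)
        assert ts.delta_tp[0, 0] == pytest.approx(est.estimate)

    def test_zero_prior_gives_zero_increments(self, nn_pilot):
        _, batch = nn_pilot
        hyper0 = default_nn_hyper(pi=0.0)
        design = DesignSpec(T=3, batch_composition=(2, 2), t0=1)
        ts = forward_simulate(batch, hyper0, "nn", design, UtilityParams(c=1.0),
                              B=3, rng_seed=2)
        np.testing.assert_array_equal(ts.delta_tp, 0.0)

    def test_horizon_reached_rejected(self, nn_pilot):
        hyper, batch = nn_pilot
        with pytest.raises(ValueError, match="t0"):
            forward_simulate(batch, hyper, "nn", DesignSpec(T=4, t0=2),
                             UtilityParams(c=1.0), B=1, rng_seed=1)

    def test_memory_guard(self, nn_pilot):
        hyper, batch = nn_pilot
        design = DesignSpec(T=2, batch_composition=(2, 2), t0=1)
        with pytest.raises(ValueError, match="cells"):
            forward_simulate(batch, hyper, "nn", design, UtilityParams(c=1.0),
                             B=10, rng_seed=1, max_cells=100)


class TestMonitorStep:
    def test_continue_when_gain_above_threshold(self, nn_pilot):
        hyper, batch = nn_pilot
        design = DesignSpec(T=10, batch_composition=(2, 2), t0=1)
        rec = monitor_step(batch, hyper, "nn", Boundary(-np.inf, 0.0),
                           UtilityParams(c=1.0), design, m=5, rng_seed=1)
        assert rec.decision == "continue"
        assert rec.rule == "boundary"

    def test_forced_stop_at_horizon(self, nn_pilot):
        hyper, batch = nn_pilot
        design = DesignSpec(T=1, batch_composition=(2, 2), t0=0)
        rec = monitor_step(batch, hyper, "nn", Boundary(0.0, 0.0),
                           UtilityParams(c=1.0), design, m=5, rng_seed=1)
        assert rec.decision == "stop" and rec.rule == "horizon_forced"

    def test_zero_prior_stops(self, nn_pilot):
        _, batch = nn_pilot
        hyper0 = default_nn_hyper(pi=0.0)
        design = DesignSpec(T=10, batch_composition=(2, 2), t0=1)
        rec = monitor_step(batch, hyper0, "nn", Boundary(0.0, 0.0),
                           UtilityParams(c=1.0), design, m=3, rng_seed=1)
        assert rec.decision == "stop"
        assert rec.delta_tp == 0.0
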