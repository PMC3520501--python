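"""Operating characteristics, fixed-design curves and model checking."""

import numpy as np
import pytest

from seqstop import (
    Boundary,
    DesignSpec,
    UtilityParams,
    compare_designs,
    default_nn_hyper,
    optimal_fixed_sample_size,
    posterior_predictive_check,
    sample_from_prior,
    simulate_sequential_study,
)
from seqstop.study import ScenarioSpec


def small_scenario(generating_pi, analysis_pi=0.3, nrep=8, c=50.0, seed=5):
    analysis = default_nn_hyper(analysis_pi)
    analysis = analysis.__class__(
        mu0=analysis.mu0, tau0=1.5, nu0=analysis.nu0, sigma0=analysis.sigma0,
        pi=analysis_pi,
    )
    return ScenarioSpec(
        generating_hyper=analysis.with_pi(generating_pi),
        analysis_hyper=analysis,
        design=DesignSpec(T=6, batch_composition=(2, 2), t0=1),
        util=UtilityParams(c=c, fdr_level=0.05),
        n_genes=300,
        nrep=nrep,
        seed=seed,
        monitor_draws=8,
    )


class TestSequentialStudy:
    def test_null_truth_stops_at_burn_in_with_no_discoveries(self):
        sc = small_scenario(generating_pi=0.0)
        oc = simulate_sequential_study(sc, Boundary(sc.util.c, 0.0), "nn")
        assert oc.mean_tau <= sc.design.t0 + 0.5
        assert oc.records["realized_tp"].mean() <= 0.5

    def test_reproducible_given_seed(self):
        sc = small_scenario(generating_pi=0.3, nrep=4)
        b = Boundary(sc.util.c, 0.0)
        a = simulate_sequential_study(sc, b, "nn")
        c = simulate_sequential_study(sc, b, "nn")
        assert a.mean_tau == c.mean_tau
        assert a.mean_utility == c.mean_utility
        assert a.records.equals(c.records)

    def test_stopping_times_respect_design_range(self):
        sc = small_scenario(generating_pi=0.3, nrep=6)
        oc = simulate_sequential_study(sc, Boundary(sc.util.c, 0.0), "nn")
        assert sc.design.t0 <= oc.mean_tau <= sc.design.T
        assert ((oc.records["tau"] >= sc.design.t0) & (oc.records["tau"] <= sc.design.T)).all()


class TestFixedDesign:
    def test_zero_cost_prefers_the_horizon(self):
        hyper = default_nn_hyper(pi=0.2)
        design = DesignSpec(T=4, batch_composition=(2, 2), t0=0)
        curve = optimal_fixed_sample_size(
            hyper, "nn", design, UtilityParams(c=0.0), B=30, rng_seed=2, n_genes=200
        )
        assert curve.n_star == design.T

    def test_prohibitive_cost_prefers_no_data(self):
        hyper = default_nn_hyper(pi=0.2)
        design = DesignSpec(T=3, batch_composition=(2, 2), t0=0)
        curve = optimal_fixed_sample_size(
            hyper, "nn", design, UtilityParams(c=500.0), B=20, rng_seed=3, n_genes=200
        )
        assert curve.n_star == 0

    def test_argmax_stable_across_seeds(self):
        hyper = default_nn_hyper(pi=0.2)
        design = DesignSpec(T=5, batch_composition=(2, 2), t0=0)
        util = UtilityParams(c=10.0)
        a = optimal_fixed_sample_size(hyper, "nn", design, util, B=100, rng_seed=1,
                                      n_genes=300)
        b = optimal_fixed_sample_size(hyper, "nn", design, util, B=100, rng_seed=2,
                                      n_genes=300)
        # the argmax may move only between n whose utilities overlap within MC error
        ua = a.utility[a.n_values == b.n_star][0]
        assert ua >= a.utility[a.n_values == a.n_star][0] - 3 * (
            a.se[a.n_values == a.n_star][0] + b.se[b.n_values == b.n_star][0]
        )


class TestCompareDesigns:
    def test_self_comparison_is_identically_zero(self):
        sc = small_scenario(generating_pi=0.3, nrep=4)
        fixed_n = 3
        table = compare_designs(
            ScenarioSpec(
                generating_hyper=sc.generating_hyper,
                analysis_hyper=sc.analysis_hyper,
                design=DesignSpec(T=fixed_n, batch_composition=(2, 2), t0=1),
                util=sc.util, n_genes=sc.n_genes, nrep=sc.nrep, seed=sc.seed,
                monitor_draws=sc.monitor_draws,
            ),
            Boundary(-np.inf, 0.0),
            fixed_n,
            "nn",
        )
        assert (table["diff_utility"] == 0).all()
        assert (table["diff_tau"] == 0).all()

    def test_overstated_prior_stops_before_fixed_design(self):
        # generating pi is half the analysis prior: sequential adapts down
        sc = small_scenario(generating_pi=0.15, nrep=8)
        table = compare_designs(sc, Boundary(sc.util.c, 0.0), 4, "nn")
        assert table["tau_seq"].mean() < 4
        assert table["diff_tau"].mean() < 0

    def test_paired_comparison_has_smaller_variance_than_unpaired(self):
        sc = small_scenario(generating_pi=0.3, nrep=10)
        table = compare_designs(sc, Boundary(sc.util.c, 0.0), 3, "nn")
        paired_var = table["diff_utility"].var(ddof=1)
        unpaired = (
            table["utility_seq"].to_numpy()
            - np.roll(table["utility_fixed"].to_numpy(), 1)
        )
        assert paired_var < unpaired.var(ddof=1)


class TestPosteriorPredictiveCheck:
    def test_self_consistent_model_stays_in_band(self, nn_hyper):
        batch = sample_from_prior(nn_hyper, "nn", 800, (5, 5), 13).batch
        table = posterior_predictive_check(batch, nn_hyper, "nn", rng_seed=1)
        # a handful of 15 quantile rows may fall outside the 95% band
        assert table["outside"].sum() <= 3

    def test_contaminated_data_is_flagged(self, nn_hyper):
        ds = sample_from_prior(nn_hyper, "nn", 800, (5, 5), 13)
        values = ds.batch.values.copy()
        rng = np.random.default_rng(2)
        spikes = rng.random(values.shape) < 0.1
        values[spikes] *= np.exp(4.0 * rng.standard_normal(spikes.sum()))
        contaminated = ds.batch.__class__(
            values=values, groups=ds.batch.groups,
            batch_index=ds.batch.batch_index, gene_ids=ds.batch.gene_ids,
        )
        table = posterior_predictive_check(contaminated, nn_hyper, "nn", rng_seed=1)
        variance_rows = table[table["statistic"] == "variance"]
        assert variance_rows["outside"].any()

    def test_reproducible(self, nn_hyper):
        batch = sample_from_prior(nn_hyper, "nn", 200, (4, 4), 3).batch
        a = posterior_predictive_check(batch, nn_hyper, "nn", rng_seed=9)
        b = posterior_predictive_check(batch, nn_hyper, "nn", rng_seed=9)
        assert a.equals(b)
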