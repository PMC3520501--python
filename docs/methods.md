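# Methods

This note documents the probability models, the decision calculus, the
numerical choices, and what the synthetic studies do and do not show.

## Models

Expression for gene `i = 1..n` and sample `j` is modelled as a two-component
mixture over a latent DE indicator `δ_i ~ Bernoulli(π)`, independent across
genes.  Under `δ_i = 0` (equally expressed, EE) the two groups share one
location parameter; under `δ_i = 1` (DE) each group draws its own, with the
gene's dispersion parameter shared either way.

**GaGa.**  `x_ij | α_i, λ_iz ~ Ga(α_i, α_i/λ_iz)` (shape/rate, mean `λ`),
`1/λ_ik ~ Ga(α₀, α₀/ν)` (mean `ν`), `α_i ~ Ga(β, β/μ)` (mean `μ`);
`ω = (α₀, ν, β, μ, π)`.  Conditional on `α_i` the inverse mean is conjugate,
so the per-group marginal is closed form; `α_i` is integrated by a fixed
64-node Gauss–Legendre rule on `log α` spanning the `1e-6 .. 1−1e-6`
quantiles of its prior.  The wide interval is deliberate: genes whose
observations pin the shape tightly place posterior mass far into the prior
tail, and truncating at the central quantiles biases the log marginal by
more than the rule's discretisation error (64 vs 512 nodes agree to 3e-14;
the interval choice moves the answer by ~1e-3).

**NN.**  On the natural-log scale `y_ij ~ N(μ_iz, σ_i²)`,
`σ_i² ~ Scaled-Inv-χ²(ν₀, σ₀²)`, and by default the conjugate
("generalized variance") mean prior `μ_ik | σ_i² ~ N(μ₀, τ₀²σ_i²)`;
`ω = (μ₀, τ₀, ν₀, σ₀, π)`.  The marginal likelihood of a gene is then a
multivariate Student-t whose determinant and quadratic form factor over mean
groups — fully closed form and vectorised over genes.  A
variance-independent mean prior (`μ_ik ~ N(μ₀, τ₀²)`) is available via
`mean_prior="independent"`; it loses conjugacy in `σ²`, which is then
integrated by the same fixed-node rule on `log σ²`.  Both variants are
validated against dense 2-D grid quadrature in the test suite.  Posterior
and predictive sampling use the conjugate variant.

**Empirical-Bayes fitting.**  `ω` is estimated once by EM on the mixture
marginal likelihood, treating `δ` as missing: the E-step computes
`v_i = P(δ_i=1 | x, ω)`, the M-step updates `π` in closed form (mean of
`v_i`) and the remaining block by bounded L-BFGS on log-transformed
parameters (a generalised M-step; the update is kept only when it improves
the weighted objective, preserving monotonicity).  Convergence: relative
log-likelihood change below 1e-6, at most 200 iterations.  Initialisation is
by moments (per-gene means and within-group variances).  Genes with
non-finite values are excluded from fitting; genes constant across all
samples are rejected by name.  Because moment-style fits tend to overstate
`π`, `adjust_pi` profiles the marginal likelihood in `π` alone (iterating
`π ← mean(v_i(π))`, which converges to the profile maximiser since the
log-likelihood is concave in `π`).

## Decisions and monitoring

Terminal decisions flag the largest gene set whose posterior expected FDR
`Σ (1−v_i)d_i / D` stays at or below the level (default 0.05): sort by `v`
descending and keep the longest feasible prefix.  Because `1−v` is
non-decreasing in that order, the running mean is non-decreasing, so the
prefix rule is the exact maximiser of `D` for distinct `v`; tied blocks
enter whole or not at all, and `D = 0` is valid with FDR defined as 0.

The sequential utility is `u = Σ δ_i d_i − c·t`.  Its posterior expectation
given a decision is `Σ d_i v_i − c·t`, so the one-step monitoring statistic
is `Δ_t(TP)`: the expected increase in `Σ d_i v_i` if one more batch were
observed, estimated by composition sampling from the posterior predictive
(draw `δ_i ~ Bernoulli(v_i)`, then the gene parameters from their
pattern-conditional posterior, then the new batch; with no data this is
exactly the prior sampler, byte-for-byte under a shared seed).

A linear boundary `(b₀, b₁)` stops at the first monitoring time `k` with
`Δ_k(TP) ≤ b₀ + b₁·k` ("strictly above" means continue; ties stop, the
cost-conservative direction).  At `k = T−1` the boundary is replaced by the
myopic rule `Δ_{T−1}(TP) − c ≤ 0`, and at `T` stopping is forced.  Along a
*simulated* trajectory, `Δ_k(TP)` is the realized one-step increment from
that trajectory's own next batch (a single-draw estimate — trajectory-level
noise averages out over the `B` trajectories of the grid search); *live*
monitoring instead averages `m` posterior-predictive draws (default 100) so
the statistic is a genuine expectation with a standard error.

**Boundary optimisation.**  `B` (default 500) trajectories are simulated to
the horizon and every grid boundary (defaults: `b₀ ∈ [0, 3c]`, `b₁ ∈ [−c, c]`,
21×21) is scored by its mean realized utility.  All boundaries within one
Monte Carlo standard error of the maximum are reported as the near-optimal
set — utility surfaces are typically flat near the top, so single-argmax
reporting would be misleading — with the member of smallest expected
stopping time as the representative (cheapest among equals).  Recomputing
the boundary as real batches accrue is supported by simply re-running on
the accumulated data.

## Synthetic study conditions

The generator draws gene parameters from the hierarchical prior and data
from the sampling model, so fitted-model checks are exactly calibrated by
construction.  Defaults (in `seqstop.presets`):

| setting | value | why |
| --- | --- | --- |
| NN μ₀, τ₀, ν₀, σ₀² | 7.0, 1.2, 6, 0.3 | log-intensities centred near 7 with gene SDs around 0.67 and typical DE log-fold-changes near 1.1 — microarray-like scale and moderate per-batch power |
| GaGa α₀, ν, β, μ | 2, 0.005, 2, 8 | raw intensities around 200 with moderately skewed gamma shapes averaging 8 |
| π | 0.05 (NN) / 0.063 (GaGa) | small DE fractions typical of two-condition screens |
| batch composition | 2 + 2 | arrays are processed a few at a time |
| horizon T | 10 batches | 20 samples per group maximum |
| FDR level | 0.05 | conventional reporting level |
| cost c | 50 | "one more batch must promise ≥ 50 new true positives" |

**Misspecified-π stress scenario** (`adaptation_scenario`): the analysis
prior holds `π = 0.3` while data are generated with `π` halved or doubled;
n = 1000 genes, `c = 50`, `τ₀ = 1.5`, one burn-in batch before monitoring
starts.  The burn-in follows standard practice — with only 2+2 samples the
FDR rule flags almost nothing, so the pre-data statistic is uninformative —
and the larger `π` and effect scale keep the expected DE count (300) well
above `c` at this reduced gene count: that is the regime in which the
stop/continue decision is non-trivial and adaptation is observable.  At
n = 1000 with `π = 0.05`, `n·π = 50 = c` and no design could ever rationally
continue.  Smaller simulations in the test suite shrink `n`, `B` and
replication counts further; the acceptance script records the sizes used
next to every number it reports.

What these simulations do **not** show: robustness to real-data features the
generator omits — batch effects, correlated genes, heavy-tailed
contamination, normalisation artefacts.  `posterior_predictive_check`
compares observed cross-gene quantiles of per-gene mean/variance/skewness
(log scale) against their simulation bands under the fitted model and flags
departures, but upstream pre-processing remains the user's responsibility;
the package deliberately consumes already-processed matrices and offers only
a positivity offset (`shift_transform`) for models that require positive
values.

## Numerical details and edge cases

* Randomness: every entry point takes one root seed; per-trajectory and
  per-replication work uses spawned child streams, so results are
  independent of execution order.  Paired design comparisons reuse identical
  per-replication seeds in both arms, making the self-comparison difference
  exactly zero and shrinking the variance of estimated differences.
* `π = 0` and `π = 1` short-circuit to exact 0/1 posteriors (no quadrature),
  making degenerate-prior identities (`Δ_t(TP) = 0` under `π = 0`) exact.
* With no data, `v_i = π` and the posterior predictive is the prior
  predictive (design from scratch, `t0 = 0`).
* Genes observed in only one group are legal; EE and DE marginals then
  coincide.  Zero-variance genes have finite marginals but are rejected by
  the fitter.
* Mixture arithmetic is done in log space throughout (`logaddexp`).
* Forward simulation refuses jobs whose gene×trajectory×horizon product
  exceeds a configurable cap rather than exhausting memory.

## Limitations

* Two groups only; multi-group comparisons and paired designs are out of
  scope (the group-label plumbing is the natural extension point).
* The terminal rule is fixed (FDR-controlling Bayes rule), not jointly
  optimised with the stopping rule; effect-size-weighted utilities are not
  implemented.
* No exact dynamic-programming solution: linear boundaries on `Δ_t(TP)` are
  an approximation, though they nest the fixed-sample and myopic designs.
* GaGa posterior sampling draws the gene shape from its posterior
  discretised on the quadrature grid (exact conjugate draws given the
  shape); the discretisation matches the marginal-likelihood resolution.
* Covariate adjustment inside the model (`ω` indexing a regression) is not
  implemented; adjust upstream and pass residual-corrected matrices.
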