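# Methods

This note records the modelling assumptions, numerical choices and known
limitations behind `marstab`.

## Model and assumptions

The community is modelled as a first-order multivariate autoregression on
natural-log abundances, X_t = A + B X_{t−1} + E_t with Gaussian
environmental shocks E_t ~ N(0, Σ).  This is the stochastic multispecies
Gompertz model: density dependence and interspecific effects are linear on
the log scale, shocks act on growth rates and are independent across days
(but may covary across taxa through Σ).  Demographic stochasticity is not
modelled; the framework targets communities large enough (10⁷–10⁹ 16S
copies per sample) that environmental and sampling variation dominate.
Time steps are one day; calendar gaps are represented as explicit missing
columns so the Markov transition structure is preserved rather than
silently bridging multi-day gaps with one-day transitions.

Observed data are relative abundances plus per-day total 16S copy counts.
Interactions estimated from proportions alone are biased (the compositional
constraint couples all taxa), so proportions are multiplied by totals
("anchored") before logging; the package includes a simulation experiment
quantifying that bias.  Exact zeros are treated as below-detection and
replaced by a configurable pseudocount (default 1 copy) before logging —
distinct from genuinely missing days, which the state-space stage handles
through the likelihood.

## Design feasibility

A p-taxon fit estimates 2p² + p parameters (A: p, B: p², Σ: p²) from
(n − 1)mp observed transitions with m replicates.  `check_design` reports
both counts and the minimal feasible length ceil((2p+1)/m) + 1, i.e.
2(p + 1) for m = 1.  The boundary n = 2(p + 1) — where transitions exactly
match parameters — is counted as feasible, matching the closed-form minimum
rather than requiring one extra day.

## Stage 1: state-space denoising

Each taxon is fitted independently with a univariate Gompertz state-space
model: latent AR(1) state (a, c, τ²) observed through m exchangeable
replicates with common observation variance.  A joint multivariate
state-space fit is deliberately avoided: it is fragile in practice because
process and observation variances trade off on likelihood ridges, and the
per-taxon decomposition keeps each optimisation 4-dimensional.

Numerics: the Kalman filter treats each replicate as a sequential scalar
update, so the filter likelihood is the exact joint normal density of all
observed replicates (verified in the tests against a brute-force joint-MVN
evaluation on short series).  The initial state prior is the stationary
distribution when |c| < 1, else diffuse with variance 10⁶.  Optimisation is
L-BFGS-B on (a, c, log τ², log obs_var) with c bounded in [−3, 3] and log
variances in [−25, 8]; five starting points are derived from a lag-1
regression of the replicate-mean series and from the within-day replicate
scatter (a direct moment estimate of the observation variance), and the
best optimum is kept; likelihood tolerance 1e-8.  The observation variance
can be held fixed (e.g. at 0) for noise-free data.  Smoothed
(Rauch–Tung–Striebel) means replace the observations downstream; smoothed
variances are retained for the bootstrap.

With a single replicate and no missing data, (c, τ², obs_var) are only
weakly identified at short n; the multi-start keeps the fit on the global
ridge optimum, but users should prefer replicated designs when observation
error matters.

## Stage 2: conditional least squares

Given a complete denoised matrix, each taxon's value at t is regressed on
an intercept and all taxa at t − 1; this is the conditional (on X₁) maximum
likelihood estimator for Gaussian shocks.  Σ is the residual cross-product
matrix divided by the number of transitions n − 1 (conditional ML; a
degrees-of-freedom divisor is available because stability metrics depend on
Σ's scale).  No sparsity or stationarity constraint is imposed on B; design
feasibility, not shrinkage, controls complexity.  Rank-deficient lagged
designs raise an error naming the collinear taxa.

Uncertainty is propagated by a parametric bootstrap that re-simulates the
fitted generative chain — MAR process noise from the estimates, then
(optionally) per-taxon observation noise from the stage-1 fits, then
re-denoising and re-fitting.  Intervals are the reflected ("basic")
bootstrap intervals 2θ̂ − q_{97.5/2.5} by default: CLS autoregressive
estimates are biased toward zero at n ≈ 70, and reflecting the percentile
interval about the estimate corrects the resulting undercoverage (measured
≈97% vs ≈87% for plain percentile intervals at the two-group fixture's
sample size); plain percentile intervals remain available.

## Stability metrics and classification

Variance proportion det(B)^(2/p); mean return rate max|λ(B)|; variance
return rate max|λ(B⊗B)| = MR² (return *times* −1/log rate are also
exposed); worst-case reactivity λ_max(BᵀB) − 1; expected reactivity
−tr Σ / tr V∞ (undefined at Σ = 0, and equal to tr(BᵀB V∞)/tr V∞ − 1 via
the Lyapunov equation — an identity the tests verify).  All are "lower =
more stable" and defined only for stationary fits.  Classification
z-scores the four metric columns, projects by PCA, and k-means-clusters
the full score matrix (50 restarts, seeded); clusters are labelled highly
stable → highly unstable by ascending mean z-scored metric, ties broken by
cluster size.  The default metric set uses the rate parameterisation and
worst-case reactivity; both choices are configurable because either
variant is defensible.

## Persistence tools

RPM (prospective): simulate n_traj trajectories of a 2-group model
(focal vs pooled rest) and report, per forecast day, the fraction with
focal proportion (computed from natural-scale abundances; ties count as
persisting) above the threshold.  The default start rule places both
groups at the focal group's stationary-mean log abundance — a 50%
starting proportion — so different communities are compared on the same
footing.  "Remain above the threshold on day t" is implemented as the
per-day marginal probability by default; a within-window first-passage
mode is also provided, and marginal probabilities bound first-passage
probabilities from above.  Defaults: threshold 0.45, horizon 20 days,
50,000 trajectories (10,000 in the CLI's `--fast` mode and in tests).

VPM (retrospective): for each day d from `fit_start` on, refit by CLS on
the prefix up to d, project a fixed window (default 10 days, threshold
0.50) from the observed state at d, and record the within-window crash
probability.  Infeasible prefixes are skipped with a warning.

Counterfactuals: `flip_interactions` negates one reciprocal off-diagonal
pair of B; `boost_growth` scales one entry of A.  Counterfactual RPM
curves are started from the *baseline* model's starting state (an explicit
x0 overrides the start rule): re-deriving the start from the modified
model would change both the dynamics and the starting point at once and
make curves incomparable.

Proportions of simulated trajectories are computed after subtracting the
per-day running maximum log abundance, so transiently explosive
counterfactual dynamics cannot overflow.

## Synthetic data generator

`generate_dataset` emulates the study design the package targets: latent
MAR(1) log abundances (500-step burn-in from the stationary mean),
per-replicate lognormal observation error on counts (Gaussian on the log
scale, default triplicates), conversion to per-day proportions and totals
(totals = sum of observed natural-scale abundances, so the proportion/total
round trip is lossless), and whole-sample missingness (a missing swab
removes all taxa of that day/replicate).  It does not emulate: taxonomic
mis-assignment, sequencing depth/compositional count noise (proportions
are exact given the log-normal abundances), below-detection truncation, or
day-to-day correlation in missingness.  Passing tests therefore show the
estimation chain is correct under the model's own assumptions, not that
real 16S + qPCR data satisfy them.

The four 3-species scenario presets encode competing pairs (1–2, 2–3), one
mutualist pair (1–3) and negative density dependence throughout, with weak
|b| = 0.05 and strong |b| = 0.5, weak-density-dependence diagonals
0.85–0.9 and strong 0.4, Σ = 0.04·I and stationary abundances at ln 10⁸.
In scenario 3 (strong negative column) the diagonals are moderated to 0.7:
with near-1 diagonals the spectral radius exceeds 1 and no stationary
distribution exists, so the preset trades a little density-dependence
contrast for a well-defined long-run regime.

## Problem sizes and seeds

Simulation-based tests and the acceptance script use deliberately modest
sizes chosen to give stable Monte-Carlo estimates: 200 replicates for the
coefficient-bias experiment, 10,000 trajectories for persistence curves,
100 outer × 300 bootstrap replicates for interval-coverage checks.  Every
stochastic routine takes a single integer seed that fully determines its
output; derived per-replicate seeds come from `numpy` seed sequences.

## Known limitations

* MAR(1) only: no higher-order lags, exogenous covariates (e.g. pH), or
  regime switching; nonlinear dynamics are captured only to first order.
* Stage-1 denoising is univariate, so cross-taxon information is not used
  when separating observation error from process noise.
* The two-group persistence tools assume the focal-vs-rest pooling is
  ecologically meaningful; pooled groups inherit a single growth rate and
  interaction pair.
* Bootstrap intervals are entrywise; no joint confidence region for B.
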