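# Methods

`popglm` analyses trial-binned spike counts from simultaneously recorded
neural populations. This note documents the models, the numerical choices
behind them, what the synthetic data emulate, and what the tests do and do
not establish.

## Encoding model

For neuron *i* with spike count *y<sub>it</sub>* in trial (bin) *t*, the rate is a
linear–nonlinear–Poisson (LNP) model with exponential link:

    lambda_it = exp( mu_i + sum_k alpha_ik f_k(x_t) + sum_{j != i} beta_ij y_jt )
    y_it ~ Poisson(lambda_it)

where `x_t` are the external covariates of trial *t*, `f_k` a tuning basis,
and `beta_ij` the *instantaneous* functional coupling of neuron *i* to the
same-bin count of neuron *j*. Three nested variants are fit per neuron:
**tuning** (alpha only), **coupling** (beta only), **full** (both). A
neuron's own count is never part of its coupling block.

Tuning bases, one per recording modality:

| kind | K | form | parameters |
|---|---|---|---|
| `cosine_direction` | 2 | [cos θ, sin θ] | direction θ in degrees |
| `cosine_direction_plus_speed` | 3 | cosines + linear speed | speed in cm/s |
| `rbf_grid_2d` | 25 | isotropic Gaussians, 5×5 grid | σ = 9 cm |
| `rbf_logfreq` | 7 | Gaussians on the octave axis over 6.4 octaves | σ = 0.64 octaves |

RBFs are unnormalised with peak 1, so weights live on the log-rate scale.
The speed term enters as a single raw column — the minimal reading of
"direction tuning plus speed tuning" for somatosensory data.

## Estimation

Weights maximise the Poisson log-likelihood minus an L1 penalty
λ·Σ c_j |w_j|. Coupling columns have penalty factor c_j = 1; cosine tuning
columns are unpenalized (c_j = 0); RBF tuning columns get c_j = 0.2 (20 %
of the coupling penalty) to stabilise the expansion; the intercept is never
penalized. Coupling covariates stay on the raw count scale (a documented
`penalty_weights` hook allows any other weighting).

The solver is a glmnet-style proximal Newton: an outer quadratic
approximation (IRLS weights) with cyclical coordinate descent and
soft-thresholding on the inner weighted least-squares problem. Details that
matter:

- **Exact zeros.** Soft-thresholding produces exact zeros; "nonzero
  coupling" and the degree statistics use exact zeros, no epsilon.
- **Monotonicity.** After every outer step the true penalized objective is
  checked and the step halved until non-decreasing; `objective_path_`
  records it.
- **Active sets.** Full KKT passes alternate with passes over the current
  nonzero set; inner sweeps stop when their quadratic gain falls below 1 %
  of the outer tolerance, so inner precision tracks outer precision.
- **Convergence.** Relative change in penalized objective < 1e-8, at most
  1000 outer iterations; non-convergence raises with diagnostics.
- **Unpenalized fits** (λ = 0) bypass coordinate descent entirely and use
  plain IRLS with direct Newton solves — cyclical descent crawls on
  strongly correlated designs (e.g. equicorrelated inputs).
- **Separation.** Linear predictors are capped at 30; a capped fit warns
  that the weights are no longer MLEs.

**Penalty path and selection.** The grid has 30 points, log-spaced over 4
decades downward from λ_max, the smallest penalty that zeroes every
penalized weight (computed from the score at the null fit, with a 2 %
guard because the bound is exact only with the unpenalized block frozen).
Selection uses 10-fold cross-validated held-out log-likelihood on
trial-wise folds. Folds are a pure function of (n_trials, n_folds, seed),
hence identical across the three variants — paired accuracy comparisons
are valid. The default selection rule is the **one-standard-error rule**
(largest penalty within 1 SE of the CV maximum, the glmnet convention):
under a null coupling design the CV curve is near-flat and a plain argmax
picks noise-favoured small penalties, reporting spurious couplings; plain
argmax remains available as `rule="max"`.

## Summary statistics

- **Spike-prediction accuracy**: cross-validated log-likelihood ratio of a
  model against a homogeneous Poisson process fitted to the same training
  folds, in base 2, divided by total covered time (n_trials ×
  bin_duration) → bits/s. The in-sample accuracy of the intercept-only
  model is exactly 0. Rates are floored at 1e-12 in likelihoods.
- **Fraction of variance explained by tuning (FVE)**: for a full-model
  fit, Var_t(tuning linear predictor) / [Var_t(tuning) + Var_t(coupling)]
  across trials. 1 ⇔ the coupling component is flat; 0 ⇔ the stimulus
  dependence is carried entirely by coupling. Both components flat → NaN
  (reported missing, not 0). This variance partition of linear-predictor
  components is this package's definition; it reproduces both limiting
  behaviours and the independence control.
- **Tuning modulation**: peak-to-peak of exp(mu + alpha·f(x)) over the
  stimulus domain, divided by bin duration (Hz). Discrete designs (8
  targets) are evaluated at their conditions, continuous domains on a
  512-point grid.
- **Tuning preference**: cosine bases → atan2(alpha_sin, alpha_cos) in
  degrees [0, 360); RBF bases → argmax of the tuning component on the
  dense grid, reported as frequency in Hz (tone axis anchored at 180 Hz)
  or place along x in cm. Flat tuning → missing.
- **Tuning overlap**: cosine similarity of two neurons' tuning weight
  vectors (baseline excluded); zero vectors → missing.
- **Spike-count correlation**: Pearson across all trials;
  `noise_correlation` recenters per condition first. Zero-variance
  neurons give missing entries. No firing-rate or bin-width correction is
  attempted.
- **Degrees**: in-degree = nonzero incoming couplings of a neuron's own
  fit; out-degree = how often its count carries nonzero weight in other
  neurons' fits; Σin = Σout by construction.
- **Hyperbolic scaling**: f(n) = f_max · n/(n + n_half) by nonlinear least
  squares with 5 multi-starts on n_half; if n_half exceeds the largest
  measured size the curve is flagged `near_linear` (the regime seen for
  weakly correlated populations).

## Decoding

With a uniform prior over a discrete stimulus set, the tuning-only decoder
uses conditional independence: log P(y|s) = Σ_i log Poisson(y_i;
λ_i(s)), computed in log space and renormalized.

The full model's coupling is instantaneous, so P(y|s) has no product form.
The coupled decoder:

1. **Gibbs-samples** the joint per stimulus (5000 retained sweeps after
   500 burn-in by default; one chain per stimulus, reused across trials,
   since the sampled joint depends only on s). Each sweep updates every
   neuron once in a freshly randomized order from its conditional Poisson
   distribution. Chains start from an independent Poisson draw at the
   tuning-component rates.
2. Uses **ordered over-relaxation** per update: draw K = 15 values from
   the conditional, sort them together with the current value, and return
   the order statistic at the rank mirrored around the current value's
   rank. Ties among equal counts (frequent for Poisson) are broken
   uniformly at random, which preserves the invariant distribution. This
   induces negative serial dependence and speeds mixing; K is a config
   flag.
3. Estimates log P(y|s) by the **chain rule**: each factor
   P(y_i | y_{<i}, s) is the Monte-Carlo mean, over Gibbs samples, of the
   analytic conditional Poisson likelihood with earlier neurons fixed at
   their observed counts and later neurons filled in from the sample.
   Neurons are taken in ascending index order (fixed; the estimator is
   ordering-dependent). Estimated marginals are floored at 1e-300 with a
   warning counter.

For small-network validation the count space can be truncated
(`max_count`), with conditionals renormalized on the truncated support;
for *symmetric* coupling the truncated joint is then an exact Gibbs
measure, which the tests enumerate directly.

## Synthetic data

The generators emulate the statistical structure of multi-electrode
trial-count recordings: heterogeneous baseline rates (default 2–10 Hz,
log-uniform), random preferred stimuli with tuning-vector norms uniform in
[0.5, 1.5], balanced condition-repeated designs (8 directions by default,
7 tones for the tonotopic case, continuous uniform positions for the
2-D place case), and 100–400 ms count windows.

- **Common input**: equicorrelated Poisson variates z (mean 1, correlation
  ρ) enter every neuron's log rate as gain·(z − 1) (default gain 0.5),
  producing noise correlations without observed coupling.
- **Correlated Poisson variates** use a Gaussian copula: equicorrelated
  latent normals pushed through the Poisson quantile function. Margins are
  exactly Poisson(mean) (variance = mean); the latent correlation is
  calibrated to the requested count correlation by bisection on the exact
  cross-moment, computed by bivariate-normal tail sums (a step-function
  integrand defeats moderate-order Gauss–Hermite quadrature, which is kept
  only as an independent test oracle).
- **Coupled populations**: an acyclic (feed-forward) coupling graph admits
  an exact directed joint and is sampled ancestrally in topological order
  — this covers the explaining-away toy chain, where downstream neurons
  inherit tuning entirely through coupling. Recurrent graphs have no
  product-form joint; their ground truth is defined by a 20-sweep Gibbs
  pass over the coupled conditionals, seeded from the uncoupled draw, with
  a fixed random neuron order per trial. (A Gibbs pass applied to a
  feed-forward graph would be order-dependent and attenuate the directed
  coupling, which is why the two cases are distinguished.)
- **LNP with correlated input**: one output neuron with rate
  exp(mu0 + w·z); weights are a sparse binary vector (zero with
  probability `sparseness`) sharing one positive value, scaled so the mean
  linear predictor is log 5 per bin — the magnitudes are otherwise
  unconstrained by the phenomena being reproduced, which are qualitative
  scaling claims.
- **Controls**: `shuffle_within_condition` permutes trials within each
  condition independently per neuron (noise correlations destroyed,
  per-condition count multisets — hence tuning curves and stimulus
  correlations — preserved bit-exactly; conditions with < 2 trials are
  skipped with a warning). `simulate_from_tuning_model` resimulates counts
  from fitted tuning-only models, giving a conditionally independent
  population with data-matched tuning.

All randomness flows from a single integer seed per generator; simulated
datasets written to disk carry their generating spec and seed in the YAML
sidecar.

What the synthetic data do **not** contain: spike-history and refractory
structure, non-Poisson dispersion, slow nonstationarities (drift,
anesthesia state), electrode-geometry-dependent coupling structure, or
continuous-time dynamics. Tests passing on these data show the estimators
and controls behave correctly under the model's own assumptions; they do
not certify behaviour under real-data violations of those assumptions.

## Problem sizes

The test suite and the reproduction script run deliberately moderate
problems — populations of 2–40 neurons, 1200–3200 trials, Gibbs chains of
1000–30000 sweeps, 10-fold CV over 30-point penalty paths — chosen so the
statistical claims (parameter recovery within stated tolerances, FVE ≥ 0.9
on independence controls, oracle agreement within 0.1 nats) are testable
with comfortable margins at interactive runtimes.

## Known limitations

- Instantaneous coupling only; no history kernels or lagged effects.
- The pseudo-Gibbs ground truth for recurrent coupling is a *definition*:
  with incompatible conditionals the stationary law depends on the update
  scheme, so cross-checks against enumeration are run on symmetric
  (compatible) networks only.
- The chain-rule estimator uses unconditional Gibbs samples for the
  not-yet-fixed neurons; its bias is quantified only empirically against
  small-network enumeration, not analytically.
- FVE is a variance partition of linear-predictor components, one of
  several defensible definitions.
- Decoding handles discrete stimulus sets only.
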