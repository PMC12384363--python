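# Methods

## Scope and data model

The package analyzes two-group event-count data (events out of trials
per cohort) together with a set of historical control studies.  Cohort
tables carry a `group` column restricted to `mutant` / `wildtype`;
group totals are exact integer sums over rows.  All analyses here use
the bundled tables: 2/329 mutant vs 0/227 wild-type mice, and two
historical lifetime wild-type studies with 0/234 and 0/69 cases.

## Exact frequentist baselines

Fisher's exact test conditions on both margins and uses the
probability-mass two-sided rule: the p-value sums the hypergeometric
probabilities of all tables whose probability does not exceed the
observed table's, with a relative tie tolerance of 1e-7 on the
comparison.  Other two-sided conventions (e.g. doubling the one-sided
tail) give different values; the probability-mass rule is the one
scipy and R use by default.  Clopper–Pearson intervals invert the
binomial tail tests through the beta-quantile identity; the lower bound
is exactly 0 at zero events.  These intervals are conservative by
construction (exact coverage ≥ nominal), which the suite verifies by
summing binomial probabilities rather than by simulation.

## Beta fitting

Two distinct summary-to-beta problems arise, and they need different
target sets:

* A **posterior-draw summary** (mean + equal-tailed interval estimated
  from samples) is fitted by minimizing the sum of squared relative
  errors of the 2.5%/97.5% quantiles and the mean over
  `(log α, log β)`, by Nelder–Mead from a moment-matched start plus a
  small fixed grid of fallback starts.  Deterministic given inputs.
* A **Wald-interval summary** from the logit scale is symmetric around
  its center, so the back-transformed point estimate is a median-type
  location, and for rare events the interval's lower bound is usually
  not jointly attainable with the center and upper bound by any beta.
  The fit therefore matches the beta's median to the point and its
  97.5% quantile to the upper bound (`use_lower=False`).

Feasibility gates: fitted quantiles must sit within 1% relative error
of their targets (5% for a matched mean).  When the summary itself is
estimated from 8000 draws, the empirical 2.5% quantile of a rare-event
posterior carries several percent relative sampling noise, so the
pooled-prior fit relaxes the quantile gate to 25% and relies on a
distribution-level check instead (KS distance between the posterior
draws and the fitted beta stays below 0.02).

Beta mixtures are fitted to draws by EM with an exact M-step: the
weighted maximum-likelihood component parameters solve the digamma
score equations `ψ(a) − ψ(a+b) = E_r[log x]`, `ψ(b) − ψ(a+b) =
E_r[log(1−x)]`, so the log-likelihood trace is provably non-decreasing.
Initialization slices the sorted draws into k quantile blocks with
moment-matched parameters (deterministic).  Convergence uses a relative
log-likelihood tolerance of 1e-8 with a 2000-iteration cap; inside
model selection a capped fit is returned with a warning rather than
raised, because an overparameterized k on unimodal data can plateau
below tolerance indefinitely while its likelihood is already flat.
The mixture size minimizes `AIC = 2(3k − 1) − 2 log L` over k = 1..k_max.

Two caveats a user should know.  First, AIC has a non-vanishing
overfit probability: on draws from a single beta it selects k = 2 in
roughly 5–10% of realizations regardless of sample size.  Second, the
MAP predictive distribution (a logit-normal mixture) is genuinely not a
beta: at 8000 draws the one-extra-component likelihood gain (ΔlogL ≈
20–30) dwarfs the AIC penalty, so selection typically returns k = 2–3
on the bundled data even though the k = 1 fit (≈ Beta(1.7, 357)) is an
excellent practical summary.  Pass `k_max=1` to force the single-beta
prior.

## Prior strategies

**Pooled.**  The common-rate model is conjugate, so "sampling" draws
independently from the analytic `Beta(1 + Σx, 1 + Σ(n − x))` posterior;
the chain layout (4 × 2000 retained by default) only fixes the draw
count.  This targets exactly the same law a sampler would converge to
and removes sampler noise from everything downstream.

**Meta-analysis.**  Continuity correction applies at zero events and,
symmetrically, at zero non-events (the latter never triggers on the
bundled data): `p_i = (x_i + 0.5)/(n_i + 1)` with
`se_i² = 1/(x_i + 0.5) + 1/(n_i − x_i + 0.5)`; interior studies use the
standard `1/x + 1/(n − x)`.  τ² is the DerSimonian–Laird moment
estimator truncated at zero (with < 2 studies it is 0 by convention,
logged).  The Wald interval uses z = 1.959964.  On the bundled studies
Q ≈ 0.37 < df = 1, so τ² = 0 and the pooling is effectively
fixed-effect.

**MAP.**  The hierarchical binomial-logit model uses, by default, a
half-normal prior with scale σ = 1/16 on τ and Normal(0, sd 2) on β₀.
The "(0, 1/16)" parameterization is read as the scale of the
half-normal: under that reading the predictive mean of the bundled
data is 0.0047 by 2-D quadrature (reading 1/16 as a variance gives
0.0051), and the MCMC reproduces it.  The sampler is an adaptive
random-walk Metropolis-within-Gibbs in the non-centered
parameterization `μ_i = τ η_i`, augmented with two structural moves:

* a translation `β₀ → β₀ + d`, `η → η − d/τ` that holds every study
  logit fixed (likelihood-preserving), which de-couples β₀ from the
  study effects when the studies are informative;
* an interweaved exact Gibbs step for τ: conditioned on the centered
  effects μ, τ² follows a Generalized Inverse Gaussian with
  λ = (1 − I)/2, χ = Σμ², ψ = 1/σ², sampled via scipy.

The base τ move is a reflected random walk on the original scale
(started at the prior scale), which avoids the heavy left tail of
log τ.  Proposal scales adapt toward 44% acceptance in 50-iteration
batches during warmup only, so retained draws come from a fixed
kernel.  Split-R̂ and ESS (via arviz) are computed for β₀ and τ;
R̂ ≥ 1.01 raises an error rather than returning silently bad draws.
Correctness checks: the τ → 0 limit matches a 1-D quadrature oracle
(KS < 0.05), and the intercept is recovered inside its 95% interval on
synthetic heterogeneous data.  One predictive draw `inv_logit(β₀ + τz)`
is formed per retained posterior draw.

## Posterior comparison and decisions

Both group posteriors are conjugate (beta, or beta mixture with weights
updated by component marginal likelihoods computed in log space), so
draws are taken directly from the posterior law.  Each group's RNG
substream is keyed to its data label, which makes the label-swap
antisymmetry (OR → 1/OR, RD → −RD) hold exactly draw by draw.  Equal-
tailed intervals use empirical quantiles with linear interpolation.
OR and RR are strongly right-skewed at these event counts; summaries
include the median alongside the mean for that reason.  Decisions:
reject the null when the 95% interval excludes 1 (OR, RR) or 0 (RD).

The null simulation replays `Binomial(n, p)` cohorts (default 100,000
replicates) and reports the frequency of ≥ k events with its Monte
Carlo standard error; `p` is taken programmatically from the wild-type
posterior mean of the comparison stage, and the exact binomial tail is
computed alongside as a cross-check.

## Synthetic data

`generate_cohorts` draws per-row binomial counts at specified true
rates; `generate_historical` draws study rates from the same
binomial-logit random-effects model the MAP stage fits
(`inv_logit(base_logit + τ·N(0,1))`).  True parameters are returned
(and optionally written) beside the data.  The generators emulate the
count structure the analysis assumes — they do not model follow-up
censoring, cause-of-death attribution, litter effects or strain-level
rate differences, so passing recovery tests demonstrate correctness of
the inference machinery under the model's own assumptions, not
robustness to real-data violations of them.

## Determinism, sizes and defaults

A single seed (default 20250819) governs every draw; independent
substreams are derived per stage.  Default draw counts mirror a
four-chain setup of 4000 iterations with half warmup (8000 retained
draws); the null simulation uses 100,000 replicates.  Test-suite runs
scale some checks down (2 × 4000 chains for reduced MCMC runs, 5–10
seeds for repetition checks, 12 synthetic studies of 2000 animals for
recovery) as a deliberate size choice; the same code paths run at any
size.  Reports are JSON with seeds and settings embedded, and identical
configurations reproduce byte-identical reports.

## Known limitations

* The framework handles exactly two groups and no covariates; per-strain
  stratified analysis is expressible through the table format but has
  no dedicated machinery.
* Monte-Carlo noise at 8000 draws leaves a few percent of spread in
  sampled-summary-derived quantities (e.g. the fitted pooled-prior β
  has an MC standard deviation near 5.4 around ~307).
* The mixture-size selection caveat above: on this class of predictive
  distributions AIC at full draw resolution prefers more than one
  component; fix `k_max=1` when a single conjugate beta prior is
  wanted.
* No survival-time modeling: cohorts are lifetime count summaries.
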