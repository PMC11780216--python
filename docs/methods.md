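# Methods

This note documents the models, the parameter choices that matter, the
numerical conventions, and what the synthetic study system does and does not
establish about real data.

## The census hurdle model

Breeding-pair counts of colonial tropical seabirds across an atoll
archipelago are heavily zero-inflated — invasive rats depress many islands
to zero — while the occupied islands span several orders of magnitude in
colony size. Neither Poisson nor negative-binomial likelihoods accommodate
both features, so abundance is modelled as a hurdle: a Bernoulli process for
whether an island × species count is zero, and a lognormal distribution for
the positive counts.

*Zero part.* `P(count = 0) = logit⁻¹(γ0 + γ_rat · rat)` with rat status the
only covariate by default (a positive `γ_rat` means rat-present islands are
more likely to host zero pairs — the documented sign convention). The
predictor set is extensible through `HurdleSpec.hurdle_predictors`, but only
rat status is supported because that is the ecological hypothesis the model
encodes.

*Positive part.* `log y ~ Normal(α_species + β_rat·rat + β_area·z(log area)
+ β_cover·z(cover) + u_island, σ)`, `u_island ~ Normal(0, τ)`. Log area
reduces the skew of island sizes; z-scoring (sample mean/sd, ddof 1, over
islands) makes coefficient priors scale-free and is stored so that scenario
predictions apply the identical transform. Species share slopes and get
their own intercepts; a per-species-slope extension is deliberately out of
scope (single joint model, as the shared-response structure of the system
suggests). Binary rat status stays 0/1, not z-scored.

*Priors.* Weakly informative defaults, all overridable via
`HurdleSpec.priors`: Normal(0, 2.5) on standardized coefficients and species
intercepts, Normal(0, 1.5) on the hurdle intercept (logit scale),
Normal(0, 2.5) on the hurdle rat coefficient, half-Student-t(3, 0, 2.5) on
σ and τ. No published prior specification was available for this system, so
reproducible defaults with an explicit override path were preferred.

*Sampling.* The two parts share no parameters and are sampled
independently. The positive part uses fully conjugate blocked Gibbs; the
half-t scale priors are represented by the Huang–Wand inverse-gamma
expansion (σ² | a ~ IG(ν/2, ν/a), a ~ IG(1/2, 1/A²)), which keeps every
conditional closed-form. The logit part uses independence
Metropolis–Hastings with a multivariate-t(5) proposal centred on the Laplace
approximation, scaled by 1.2; with 2–4 coefficients and a proper prior this
yields acceptance rates around 0.7. A Metropolis acceptance rate below
`min_mh_acceptance` (default 0.05) raises a diagnostics error carrying the
per-chain rates — the analogue of a divergence check for this sampler
family. Default schedule: 4 chains × 3000 iterations with 1000 warmup.

*Diagnostics.* Split-R̂ is computed from the classic between/within
variance ratio on half-split chains; values below 1 (possible when the
between-sequence variance hits its noise floor) are clamped to 1, and
all-constant chains return the sentinel 1 (equal across chains) or ∞
(unequal). The fit warns, not errors, above R̂ = 1.01. Posterior predictive
checks replicate one dataset per draw and compare the zero fraction, the
maximum count and the mean log positive count. PSIS-LOO uses arviz with the
pointwise log-likelihood (zeros contribute `log P(zero)`; positives
`log(1−P(zero))` plus the lognormal density conditional on the fitted
island intercept, with the 1/y Jacobian) and a relative efficiency computed
from the ESS of the pointwise log-likelihood draws. Gibbs mixing for τ is
slower than for location parameters; at 25 islands the worst R̂ is typically
1.03–1.07 and posterior summaries are stable, at 200 islands R̂ < 1.01.

## Scenario predictions

Restoration scenarios fix rat status to absent and native cover to 25, 50
or 75% (≈ lower quartile, mean and upper quartile of native cover across
the archipelago). Predictions use the lognormal component only — the hurdle
is bypassed, because the question is the abundance an island could support
once the zero-forcing pressure is removed. Two documented conventions,
chosen per call:

- `mean_type="mean"` (default): `E[y] = exp(μ + σ²/2)`, the lognormal mean
  including residual variance; `"median"` gives `exp(μ)`. The fitted-value
  route is genuinely ambiguous about residual-variance inclusion, so both
  are exposed and the mean documented as default.
- `island_effect="integrate"` (default) adds τ²/2, i.e. the marginal mean
  for a *new* island state — appropriate because a restored island's
  counterfactual intercept is unobserved; `"zero"` conditions on u = 0.

Predictions are continuous pairs (rounding is presentation-level), strictly
positive, and additive across islands within each draw, so totals and fold
changes carry full posterior uncertainty. Fold change divides predicted
total pairs per draw by the observed current total (a plain count); a zero
current total raises an error rather than returning ∞.

## Bioenergetics

Per breeding phase, `FMR = exp(a + b·ln(mass_g) + c·|latitude|)` kJ/day;
daily intake divides by prey energy density (5.5 kJ/g wet mass) times
assimilation efficiency (0.75); annual consumption sums intake × phase
duration × pairs × 2 adults over phases and converts to tons at 10⁶ g/ton.
Only breeding adults within the breeding season are counted: these species
disperse from the colony outside it, and chick provisioning is not added as
a separate term (a config hook exists via the phase table). The shipped
phase durations partition the season, so the phase-sum formulation equals
intake × season length. The chain is degree-1 homogeneous in abundance, so
posterior abundance draws pass through unchanged in shape.

## Prey supply and sustainability

Standing stock inside a foraging disc is the time-mean of
`Σ density × cell_area` over grid cells whose centers fall within the
great-circle radius (haversine, spherical Earth R = 6371 km;
latitude-corrected cell areas). Cell-center membership, with no
partial-cell clipping, biases the disc area by O(resolution); at 0.25° and
500 km radius the error against the analytic πr² is ~0.03%, and the
extraction is exactly monotone in radius and linear in density.

Production multiplies standing stock by P/B turnover: 3.4 /yr at trophic
level 3.0 and 1.4 /yr at TL 3.7 — the *low* production bound uses the
*high*-TL ratio. The sustainable-extraction threshold is 25% of production
per bound, equivalently 0.35–0.85 × standing biomass per year. Exceedance
is strict (`consumption > threshold`); a value exactly at the bound does
not count. Assessments use the annual mean field (not month-matched to
breeding phenology), the 1200 km all-species radius for totals, and each
species' own maximum radius for species-level checks; range overlap between
species is not double-count-corrected — totals are compared against the
shared 1200 km pool.

## Nutrient flux

kg N yr⁻¹ per island = Σ_species pairs × 2 × (a·mass^b g dry guano/day) ×
guano-N fraction × season days / 1000. Defecation and N-content constants
are configuration data; the code fixes only the functional form. A
colony-residence multiplier (default 1.0 — the full season-day product)
scales for time spent defecating away from the colony. Scenario budgets
keep the census contribution of non-focal species everywhere and of focal
species on non-scenario islands, and substitute posterior draws for focal
species on scenario islands; the result is never below the non-focal
baseline. Budgets are degree-1 homogeneous in abundance and season length,
and per-hectare rates divide by island area exactly.

## Reef response

Each metric (coral growth, reef fish biomass, parrotfish grazing,
parrotfish bioerosion) gets its own lognormal regression on log(N input per
ha) with an island random intercept over within-island replicates —
replicates are never pre-averaged, and no island effect is shared between
metrics (the models are fit independently, matching the separate-model
design). Islands with zero nitrogen at prediction time are floored at half
the smallest positive training value (configurable); the training data
contain no zero-nitrogen islands to dictate behaviour.

Scenario percent change per draw and island is
`100·(exp(β·Δlog N) − 1)` — the intercept, island effect and variance
terms cancel, making percent changes invariant to the metric's units.
Because aggregation order is genuinely ambiguous (islands-within-draw vs.
draws-within-island), `pct_change_summary()` reports both; the grand means
coincide. Nitrogen budgets are reduced to per-island posterior means before
the reef stage — reef-model uncertainty is carried draw-wise, nutrient
uncertainty is summarized first (the two posteriors have unrelated draw
dimensions, and pairing them arbitrarily would fabricate correlation).
Upscaling multiplies the unweighted island mean of predicted kg/ha by
4380 km² × 100 ha/km² (a per-island reef-area weights hook exists but no
weights ship).

## Synthetic data: what it does and does not show

The generators mirror the structure the models assume: hurdle zeros
concentrated on rat islands (logit intercept −2.0, rat effect +2.8 —
chosen so the marginal zero rates are ~12% / ~69% on rat-free / rat-present
islands), rounded-lognormal positive counts with log-area slope 0.9 and
cover slope 1.5, island sd 0.5 and residual sd 0.7 (order-of-magnitude
choices — no empirical inter-island variance decomposition was available,
and they are deliberately labelled as such), ~25 islands of 1–500 ha with
Beta(1.5, 2) native cover clipped to [0.03, 1] (mean ≈ 0.43, range
3–100%). The prey field is lognormal around 0.5 t/km² with CV 0.4 and a
200 km Gaussian correlation length over 15°S–2°N, 60°E–82°E at 0.25°; the
density was set so that a 1200 km disc holds ≈ 2 × 10⁶ t standing stock,
the magnitude a size-structured ocean ecosystem model gives for this
region. The reef survey uses log-slopes 0.15–0.35 across metrics with
4 replicates per island.

Passing tests on these data establish *internal* correctness: the samplers
recover generating parameters with nominal interval coverage, the
predictive machinery is self-consistent, and every deterministic identity
holds. They do not establish that real censuses follow a lognormal with
these variances, that prey fields are lognormal with Gaussian correlation,
or that the stand-in energetic and excretion constants are accurate — the
species YAML is explicitly synthetic and must be replaced with transcribed
published values for substantive use.

Counts are rounded lognormal draws, not Poisson-lognormal: the analysis
likelihood is lognormal on abundances, and a latent-count layer would
mismatch it. Rounding can in principle produce zeros outside the hurdle,
but with the default coefficient scales positive means are ≫ 1 and this
has no practical effect.

## Problem sizes and numerical conventions

- Parameter-recovery battery: 20 replicates at 200 islands (600
  observations), 4 × 3000 MCMC; pooled 95%-interval coverage of the 10
  generating parameters is the test statistic.
- Exact leave-one-out oracle: 12 islands (36 observations), one refit per
  held-out observation at 4 × 1500, compared to PSIS-LOO within 2 SE.
- Reef recovery: 20 replicates at 40 islands × 4 replicates, true slope
  0.4.
- End-to-end smoke runs: 10 islands, 2 × 700 iterations.
- Ties: exceedance is strictly greater; R̂ is clamped at 1 from below;
  degenerate (zero-variance) continuous covariates error, while a
  non-varying binary rat covariate is dropped with a warning so rat-free
  simulations remain fittable.
- All randomness descends from one root seed: the pipeline fans out fixed
  per-stage subseeds (stable under stage disabling), the samplers spawn
  per-chain generators from `SeedSequence`, and repeated runs produce
  byte-identical summary JSON.

## Known limitations

- No population dynamics: scenario abundances are equilibrium capacities,
  not recovery trajectories (no immigration, recruitment or time-to-recover
  modelling).
- PSIS-LOO at large n: with 600 observations, a well-specified fit still
  shows occasional Pareto k just above 0.7 for genuinely influential
  observations (e.g. rare positive counts on rat-present islands). This is
  a property of obs-level importance sampling with conditional likelihoods,
  not a sampler defect; moment-matched or refit-based LOO for such points
  is not implemented.
- Gibbs mixing for the group-sd parameter τ is slower than gradient-based
  samplers at small island counts; summaries are stable but R̂ for τ can
  reach ~1.06 at 25 islands under the default schedule.
- The reef stage consumes nitrogen budgets as posterior means; nutrient and
  reef uncertainties are not jointly propagated.
- Prey extraction ignores bathymetry, seasonality-phenology matching, and
  competing consumers (sharks, tunas); the sustainability rule is a single
  fraction-of-production criterion.
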