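# Methods

This document specifies the statistical model, estimators and numerical
choices implemented in `cancerineq`, in enough detail to reimplement them.

## 1. Data model

The unit of analysis is a stratum cell indexed by age band *a*, calendar
year *t*, gender *g*, deprivation decile *d* (1 = most deprived, 10 = least)
and region *r*. Each cell carries an event count `C` (cancer registrations
or deaths) and a person-year exposure `E > 0`. Tables are validated on
construction (`CountTable`): non-negative counts, positive exposures,
deciles in 1..10, declared region and gender labels, age bands belonging to
a declared scheme, and no duplicate keys. Rows are canonically sorted so
that two tables with the same cells compare equal regardless of input
order.

Age bands are five-year closed bands (`"45-49"`, midpoint lower + 2) with
an open terminal band (`"85+"`, midpoint fixed at 90). Registration data
extending past 85 (e.g. `"90-94"`, `"95+"`) are merged into the terminal
band on read, summing counts and exposures, because deaths and populations
stop at 85+.

CSV round trips are bit-exact: files are written with
`float_format="%.17g"` and read with `float_precision="round_trip"`. Both
are required; either alone loses the final ulp of exposures.

## 2. Hierarchical Poisson-lognormal model

Per cell *i*:

    C_i | θ_i ~ Poisson(θ_i E_i)
    θ_i ~ Lognormal(x_i'β, σ²)
    β_j ~ Normal(0, 10⁴)
    σ² ~ Inverse-Gamma(1, 0.001)

The latent log-rate η_i = log θ_i has a Normal(x_i'β, σ²) prior, making β
and σ² conditionally conjugate given η.

### Design matrix

Deterministic column order: intercept; age (categorical sum-to-zero
contrasts, or a numerical midpoint term); year as standardised polynomial
powers up to degree 3; gender, deprivation and region as sum-to-zero
factors; interactions as row-wise outer products of the parent encodings;
finally the AAD covariate and its region interaction (mortality models
only). Sum-to-zero contrasts use L−1 columns with the last level's
indicator replaced by −1 on every column, so full-level effects always sum
to zero and are recoverable by `full_level_effects`.

Year is standardised over the *distinct* study years with the population
(divide-by-n) standard deviation: for 2001–2016, mean 2008.5 and
sd √(255/12), so 2001 maps to −1.6270. Repeated rows do not change the
mapping.

### Sampler

Metropolis-within-Gibbs:

- **η update**: all cells simultaneously, by independent random-walk
  Metropolis steps (the η_i are conditionally independent given β, σ²).
  Per-cell proposal scales adapt toward 0.44 acceptance every 50 iterations
  during burn-in only, preserving ergodicity afterwards.
- **β update**: exact draw from the conjugate multivariate normal with
  precision `X'X/σ² + I/10⁴`, via a single Cholesky factorisation and
  triangular solves.
- **σ² update**: exact Inverse-Gamma(1 + n/2, 0.001 + ½‖η − Xβ‖²) draw.

Initial β is a ridge-stabilised Poisson ML fit with offset log E; initial
η = log((C + ½)/E). Default chain: 20,000 iterations, 5,000 burn-in,
thin 5. Identical seed and configuration reproduce draws bit for bit.

## 3. Marginal quantities

**Moments.** With m = E·exp(x'β + σ²/2), the marginal count mean is m and
the marginal variance is

    Var[C] = m (1 + m (exp(σ²) − 1)),

the factor being the squared coefficient of variation of the lognormal
rate. A variant formula `m (1 + m exp(σ² − 1))` circulates in print; it is
dimensionally inconsistent (it does not reduce to the Poisson variance at
σ² = 0) and is provided only as the `variance_mode="literal"` toggle
of `pearson_residuals` for comparison. The corrected form is the default
everywhere and is verified against Monte-Carlo simulation.

**Marginal likelihood.** p(C|β,σ²) integrates η out of each cell by
*adaptive* Gauss–Hermite quadrature: the rule is centred at the mode of the
per-cell integrand (found by damped Newton on the strictly concave
objective) and scaled by the Laplace standard deviation
`(E e^η̂ + 1/σ²)^{-1/2}`. A prior-centred rule is badly biased for large
counts because the likelihood width in η shrinks like 1/√C; the adaptive
rule with 25 nodes agrees with brute-force Monte-Carlo integration within
MC error and is stable under node refinement to <1e-6 nats. At σ² = 0 the
exact Poisson log-likelihood is returned.

## 4. Model selection and diagnostics

**DIC** is computed on the marginalised deviance D(β,σ²) =
−2 log p(C|β,σ²): DIC = D(β̄,σ̄²) + 2p_D with p_D = mean deviance minus
deviance at the posterior means (up to 400 evenly spaced draws).

**Bayes factors** use the Schwarz approximation: BF₁₀ = exp(−½(BIC₁ −
BIC₀)) with BIC = −2·max marginal log-likelihood + (p+1)·log n, maximised
by L-BFGS-B over (β, log σ²) from the posterior means; the +1 counts σ².
This is a documented large-sample approximation, not an exact marginal
likelihood ratio.

**Forward selection** is a greedy single pass from the intercept-only
model, visiting candidates in the given order (main effects before the
interactions that involve them). A candidate is accepted when ΔDIC < 0 or
BF > 3 against the current model. Interactions whose parents were not
retained are skipped with a note. The full trace (term, DIC, ΔDIC, BF,
decision, note) is emitted for audit. Note that the ΔDIC < 0 rule has
≈16% type-I probability for a 1-df noise term (P(χ²₁ > 2)); this is a
property of DIC, not of the implementation.

**Pearson residuals** r = (C − m̂)/√(V̂ar[C]) use posterior-mean plug-ins;
on self-simulated data of ~10⁴ cells they have mean ≈0 and variance ≈1.

## 5. Age standardisation and gap statistics

The European Standard Population 2013 table is embedded (checksum
100,000). Scheme bands receive the summed ESP weight of the five-year
groups they cover; an open terminal band absorbs all groups from its lower
bound (85+ → 1500 + 800 + 200 = 2500).

Per posterior draw and per (year, decile, gender, region):

    ASR = 100000 · Σ_a w_a θ_a / Σ_a w_a.

Gap statistics are evaluated **draw by draw and then summarised** (never
max/min of posterior means, which biases the gap down and understates
uncertainty):

- **AD** — highest minus lowest decile ASR within a year/region;
- **AC** — ASR(t₁) − ASR(t₀) per decile/region;
- **RD** — ratio of highest to lowest decile ASR.

All intervals are equal-tailed 95% quantiles over draws.

## 6. Average age-at-diagnosis (AAD) and delay impacts

Per draw and per (t, d, g, r):

    AAD = Σ_a a · θ_a · w_a / Σ_a θ_a · w_a

with band midpoints *a* and ESP weights *w*; invariant to rescaling θ.
Values are population-weighted over study years to one cross-sectional
value per (d, g, r), then standardised to zero mean and unit population SD
*s* (years).

In the mortality model the standardised AAD enters with slope γ (plus
sum-to-zero regional deviations γ_r when `AAD:region` is included). A
diagnosis delay of δ years multiplies mortality rates by
exp((γ + γ_r)·δ/s); the reported impact is 100·(factor − 1) percent, per
draw, with 95% intervals. Consequences:

- impacts compound exactly: the δ-year factor is the (δ/2)-year factor
  squared;
- a 12-month impact of 23.56% implies 11.16% at 6 months and 5.43% at
  3 months; 3.39% implies 1.68% at 6 months;
- a sustained latency drift of k years per calendar year over an h-year
  horizon equals a single delay of k·h years (7%/yr over 4 yr → 31.1%).

**Regional contribution**: per draw, (γ + γ_r)/γ̄ where γ̄ is the mean
slope over regions (= γ under the sum-to-zero constraint); flagged
unstable when γ̄'s sign varies in >5% of draws.

**Uncertainty propagation** (`delay_impact_pooled`): the AAD covariate is
itself an estimate; plugging in its posterior mean understates impact
uncertainty. The mortality model is refitted for several evenly spaced AAD
posterior draws and the impact draws pooled — a multiple-imputation
approximation that restored ≈95% coverage in simulation (plug-in gave
≈70%). Identification note: AAD varies across deciles/regions only if the
incidence age profile does (age:deprivation / age:region interactions);
with pure main effects the slope is nearly unidentified.

## 7. Synthetic-data generator

`ScenarioConfig` freezes a stratum grid, planted effects (scalars for
intercept/year powers, full-level sum-to-zero vectors for factors, side
pairs for interactions), σ², exposure scale and seed. Exposures follow a
declining age profile above 60 with lognormal jitter; randomness is split
into three `SeedSequence` substreams (exposures, latent noise, counts) so
each stage is independently reproducible. `make_delay_scenario` plants a
known AAD slope on the mortality log-rates via the standardised true AAD,
giving ground truth for the full incidence → AAD → mortality chain.

## 8. Pipeline

`run_pipeline` executes data (simulate or load) → incidence fit (optional
forward selection) → standardisation and gaps → AAD → mortality fit →
delay impacts, writing tidy CSVs plus a JSON manifest (seed, config hash,
stage status, file list). Reruns with the same configuration are
byte-identical. CLI exit codes: 0 success, 2 validation/configuration
error, 3 numerical failure.

## 9. Known limitations

- Single-chain inference; convergence is assessed in tests by two-seed
  potential-scale-reduction checks, not in production runs.
- The Schwarz Bayes factor ignores prior odds and is asymptotic in n.
- DIC-based selection retains 1-df noise terms ≈16% of the time by
  construction.
- No spatial priors; regions are exchangeable fixed effects.
- AAD is a cross-sectional summary; cohort-level interpretation of delay
  impacts assumes the age profile shift is the causal pathway.
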