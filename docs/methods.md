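# Methods

## Background and model

Short-term air-pollution epidemiology estimates a slope β linking a daily
exposure series xₜ to a daily outcome yₜ while controlling for temporal
confounding.  Two broad strategies exist:

1. **Time-series regression**: model yₜ on xₜ plus a smooth function of
   time (natural cubic spline with a fixed df per year) and day-of-week.
   Its Achilles heel is *concurvity*: periodic structure shared by exposure
   and outcome at frequencies the spline cannot track (periods of a few
   months under 6 df/year) leaks into β.
2. **Case-crossover on counts**: group days into small calendar strata and
   eliminate each stratum's level.  Confounding that is constant within a
   stratum — everything slower than the window length — vanishes exactly.
   The shorter the window, the more temporal structure is removed; the
   two-day window (CC2D) is the shortest possible for daily data.

### Conditional Poisson likelihood

With Poisson counts and log μᵢ = αₛ + ηᵢ (ηᵢ = βxᵢ + γ′zᵢ), conditioning on
the stratum total Yₛ yields a multinomial distribution over the stratum's
days with probabilities pᵢ = e^{ηᵢ}/Σⱼ e^{ηⱼ}; the αₛ cancel.  The
log-likelihood, score and observed information are

    ℓ = Σₛ [ Σᵢ yᵢηᵢ − Yₛ log Σᵢ e^{ηᵢ} ]
    U = Σₛ Σᵢ (yᵢ − Yₛpᵢ) xᵢ
    I = Σₛ Yₛ [ Σᵢ pᵢxᵢxᵢ′ − (Σᵢ pᵢxᵢ)(Σᵢ pᵢxᵢ)′ ]

I is a non-negative mixture of covariance matrices, so ℓ is concave; the
optimizer verifies positive semidefiniteness of I at every iterate and
aborts otherwise.  On strata of size two with outcomes {0, 1} and total 1
this reduces to the conditional logistic (matched-pair) likelihood, the
classical case-crossover formulation on individual events; the count form
is the same inference with one record per day rather than per event.

Strata that cannot inform the slope are dropped beforehand
(`informative_strata`): fewer than two records, constant exposure, or —
Poisson only — zero total outcome.  Singleton and zero-total strata
contribute identically zero to ℓ for any parameter value, so removing them
changes nothing; a constant-exposure stratum contributes no information
about β but does carry information about within-stratum covariates such as
day-of-week, so on models with covariates filtering can shift the covariate
estimates (and, for the Gaussian fit, moves that stratum's outcome
variation out of the residual).  The test suite asserts the exact
invariance on exposure-only models, which is where the claim is exact.

### Conditional Gaussian fit

For continuous responses the stratum-eliminated model is least squares with
one intercept per stratum.  By Frisch–Waugh this equals OLS on
within-stratum-centered response and regressors; `ccwin` computes it that
way (no indicator matrix is ever formed).  Standard errors use residual
df = n − #strata − #slopes, the convention of a fixed-effects OLS with
explicit dummies.  Whether a dispersion-adjusted or unit-variance SE is the
"right" convention for stratum-eliminated Gaussian fits is genuinely open;
the residual-df choice is conservative and matches the dummy-variable
oracle exactly, which makes it testable.  No overdispersion/quasi-likelihood
scale is modelled for the Poisson family; this is a documented limitation.

### Stratum schemes

| scheme | stratum | sizes | day-of-week handling |
|---|---|---|---|
| CC2D | year : day pair (1,2),(3,4),… | 1–2 | covariate |
| CC3D | year : day triple | 1–3 | covariate |
| CC2W | year : two-week block : dow | 1–2 | absorbed by design |
| CC2CW | year : chained week pair : dow | 1–2 | absorbed by design |
| CCM | year : calendar month : dow | 4–5 | absorbed by design |

A 365-day year gives exactly 183 CC2D strata (182 pairs + 1 singleton).
Weeks are numbered from each year's day 1 in 7-day blocks (the stratum
construction anchors at day 1 regardless of weekday, which makes strata
reproducible); day-of-week itself is always the true calendar weekday.
Trailing days that do not fill a block form short strata rather than being
merged backward.  Under the calendar year rule, leap years run day-of-year
1–366 and Feb 29 participates normally in its pair/triple — no day is
silently dropped.  The `fixed365` year rule serves simulated series built
from 365-day years; it requires a day span divisible by 365 unless a
partial trailing block is explicitly permitted.  Stratum ids are
deterministic strings (`"<year>:<block>[:<dow>]"`), so runs are
bit-reproducible.

For CC2CW, chained week pairs (1,2),(2,3),… duplicate each interior week's
records into two strata.  This nearly doubles the record count and shrinks
the reported standard errors, but those SEs are *naive*: the duplicated
records are not independent, so the chained scheme's intervals should be
read as optimistic.  The package reports them as computed and leaves the
caveat here.

Day-of-week dummies use treatment coding with Monday as reference (the
choice affects only the covariate estimates, never β).  Covariates that are
constant within every stratum (within-stratum range < 1e-12) are detected
numerically and dropped with a notice — under CC2W/CC2CW/CCM the design
itself adjusts for day-of-week, and the conditional likelihood cannot
identify it.

### Natural cubic spline basis

The spline basis (used for the smooth function of time in the GLM
comparator and for temperature adjustment) is a natural cubic spline with
boundary knots at the data min/max and interior knots at equally spaced
quantiles.  It is built from the cubic B-spline basis on those knots,
constrained to zero second derivative at both boundaries (hence linear
extrapolation beyond them) and zero value at the left boundary (removing
the constant so the df columns complement an explicit intercept).  Tests
verify it spans the same space as an independently constructed
truncated-power natural basis and that extrapolation is exactly affine.
Temperature knots are computed on the analysis dataset's own temperature
distribution.

### Optimization and numerics

Newton–Raphson with analytic derivatives; convergence when max |score|
< 1e-8 or max |step| < 1e-10, cap 100 iterations, step-halving on any
likelihood decrease.  A monotone likelihood (e.g., a single 0/1 pair with
concordant exposure) drives the coefficient to ±∞ while the score decays
to zero, so score convergence alone would mislabel it; any coefficient
exceeding 15 in absolute value is reported as non-convergence with the
drift direction.  Wald 95% intervals (β ± 1.96·SE) throughout.

## The simulator

`simdata` generates 10-year (3650-day) series with

    xₜ = Σₖ aₖ sin(2πt/Pₖ + φₖ) + eₜ
    yₜ = β·xₜ + Σₖ bₖ sin(2πt/Pₖ + φₖ + δ) + εₜ,   β = 1

Scenarios: Sim1 has periods {183, 75} days; Sim2 adds {105, 68}; Sim3 is
Sim2 with AR(1) background noise replacing white; Sim4 is Sim3 with both
noise scales doubled.  Defaults (all overridable on `SimulationConfig`):

| parameter | default | why |
|---|---|---|
| aₖ, bₖ (amplitudes) | 2.0 | periodic variance Σaₖ²/2 large relative to noise, so confounding dominates the unconditional fit |
| δ (phase offset) | 2π/3 | cos δ = −½ makes the confounder genuinely correlated with exposure (δ = 0 would be pure concurvity with no offset; δ = π with aₖ = bₖ would cancel exactly in y) |
| φₖ | (0, 1.3, 2.1, 0.7) rad | arbitrary fixed values; deterministic signal means only noise varies across samples |
| exposure noise sd | 1.0 | day-to-day exposure variation that identifies β within pairs |
| outcome noise sd | 0.5 | keeps the CC2D sampling sd of β̂ near 0.01 at n = 3650 |
| AR(1) ρ (Sim3/4) | 0.6 | serially correlated background, marginal sd preserved |
| Sim4 scale factor | 2.0 | "same structure, bigger noise" variant |

Why these choices work: within a two-day stratum a sinusoid of period P
changes by ≈ 2π/P of its amplitude, so with P ≥ 68 the confounder
contributes < 0.2 sd of within-pair variation against white exposure noise
of sd √2 — the pair contrast is nearly clean, and the CC2D slope lands
within a few percent of 1.  The unconditional fit instead sees the full
periodic variance; a 60-df spline over 3650 days (knot spacing ≈ 61 days)
absorbs much of the 183-day component but little at 68–105 days, so the
surviving shared periodicity attenuates the slope by roughly
Σₖ aₖbₖ cos δ (1−Rₖ)/2 over the residual exposure variance — about a 0.3–0.45
attenuation at these defaults, as observed.

Per-sample randomness comes from `numpy.random.default_rng([seed,
sample_index])` — counter-based, parallel-safe, bit-reproducible.  The
latent decomposition (periodic parts, confounder, noises) is stored on each
sample and the outcome reconstructs from it exactly.

**What the simulator does not emulate:** real series have counts (the
simulated outcome is Gaussian), day-of-week structure, missing days,
heteroscedastic and overdispersed noise, and confounders that are not sums
of fixed sinusoids.  Passing the simulation study therefore demonstrates
the designs' behaviour under stationary periodic confounding with known
truth — not performance on any particular real dataset.  The count-data
path is exercised separately with Poisson-generated series (multiplicative
slope recovery and CI coverage).  For real analyses, `dataio` reads
configuration-driven CSVs and `run_epi_analysis` fits the conditional
Poisson model with temperature spline and exposure lag; a template config
for a Chicago-style mortality analysis (date, cvd, death, temperature,
pm10, o3 columns) is the intended usage, with no data bundled.

## Study harness

`run_simulation_study` fits each requested method to each sample, excludes
and counts non-converged fits (never imputes), and summarizes betas and SEs
as {min, 1st quartile, median, mean, 3rd quartile, max} plus the sd of
betas.  Quartiles use linear interpolation between order statistics (the
numpy default); the convention is recorded in the run manifest.  The
problem sizes used by the test suite and the acceptance script — 50 samples
per scenario, 100 replicates for the count-model properties — were chosen
as the smallest sets whose Monte-Carlo error is comfortably below the
effects being demonstrated.

## Known limitations

- Naive SEs under record duplication (CC2CW), as above.
- No overdispersion adjustment for the Poisson family.
- No event-level referent sampling (the classical ±7k-day control selection
  within month is background, not implemented); no GAM/penalized smoothers.
- The 95% level and lag 0 are defaults, not estimates; both are surfaced in
  the interfaces.
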