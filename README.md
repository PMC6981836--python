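# ccwin — short time-window case-crossover analysis of daily series

`ccwin` estimates short-term associations between a daily environmental
exposure (an air-pollution concentration, say) and a daily health outcome
(death counts, or a continuous response) using **case-crossover designs on
daily counts**: days are grouped into small calendar strata and the slope is
fitted by a conditional regression in which every stratum's nuisance level is
eliminated rather than estimated.  The shortest variant, **CC2D**, pairs
consecutive days — (1, 2), (3, 4), … within each year — so anything that
varies slowly over time (season, long-term trends, slow confounders) is
removed *by design*.  This is exactly the regime in which the classical
time-series alternative — a GLM with a natural cubic spline of time at a
fixed df/year — can fail badly when exposure and outcome share mid-frequency
periodic structure.

## The model

For stratum *s* with days *i ∈ s*, outcome *y*, exposure *x* and covariates
*z* (day-of-week dummies, a temperature spline):

* **Conditional Poisson** (daily counts).  Conditioning the Poisson model
  log μᵢ = αₛ + βxᵢ + γ'zᵢ on each stratum total Yₛ = Σᵢ yᵢ gives a
  multinomial likelihood per stratum in which αₛ cancels:

  ℓ(β, γ) = Σₛ [ Σᵢ yᵢηᵢ − Yₛ log Σᵢ exp ηᵢ ],  ηᵢ = βxᵢ + γ'zᵢ.

  ℓ is concave; `ccwin` maximizes it by Newton–Raphson with analytic
  gradient and Hessian.  With strata of size two and 0/1 outcomes this is
  conditional logistic regression on matched pairs — the classical
  case-crossover likelihood — so the count formulation is the same design
  with far fewer records.

* **Conditional Gaussian** (continuous response).  OLS with one intercept
  per stratum, computed by within-stratum centering (Frisch–Waugh); SEs use
  residual df = n − #strata − #slopes.

Stratum schemes: `CC2D` (year : 2 days), `CC3D` (year : 3 days), `CC2W`
(year : two-week block : day-of-week), `CC2CW` (chained, overlapping
two-week blocks — each interior week serves two strata, nearly doubling the
records and narrowing the naive confidence intervals), and `CCM`
(year : month : day-of-week, the standard time-stratified referent scheme).
The comparator `GLM6`/`GLM12` is the unconditional regression on exposure +
day-of-week + a natural cubic spline of time with 6 or 12 df per year.

A built-in simulator generates 10-year (3650-day) exposure–response series
with true slope β = 1 and sinusoidal components at periods of 183, 75, 105
and 68 days shared (with a phase offset) between exposure and outcome — a
seasonal-confounding structure that defeats fixed-df spline adjustment while
leaving the two-day design nearly unbiased.

## Worked example

Run the simulation study for scenarios 1–2 with the two-day design and the
6 df/year spline GLM, 10 samples each:

```sh
ccwin study --sims 1,2 --methods cc2d,glm6 --n 10 --seed 1 --out demo/
```

prints (and writes to `demo/summary_tables.csv`):

```
| Method | Parameter | Beta1 | Beta2 | SE1 | SE2 |
|---|---|---|---|---|---|
| CC2D | Minimum | 0.9757 | 0.9731 | 0.0117 | 0.0118 |
| CC2D | 1stQuartile | 0.9834 | 0.9757 | 0.0118 | 0.0120 |
| CC2D | Median | 0.9894 | 0.9812 | 0.0120 | 0.0122 |
| CC2D | Mean | 0.9916 | 0.9858 | 0.0120 | 0.0122 |
| CC2D | 3rdQuartile | 1.0006 | 0.9960 | 0.0121 | 0.0123 |
| CC2D | Maximum | 1.0127 | 1.0050 | 0.0124 | 0.0125 |
| GLM6 | Minimum | 0.6553 | 0.5651 | 0.0132 | 0.0138 |
| GLM6 | 1stQuartile | 0.6645 | 0.5720 | 0.0133 | 0.0139 |
| GLM6 | Median | 0.6662 | 0.5755 | 0.0133 | 0.0140 |
| GLM6 | Mean | 0.6666 | 0.5743 | 0.0133 | 0.0140 |
| GLM6 | 3rdQuartile | 0.6701 | 0.5767 | 0.0134 | 0.0140 |
| GLM6 | Maximum | 0.6777 | 0.5828 | 0.0135 | 0.0142 |
```

The true slope is 1.0 in every sample.  The two-day case-crossover fit
(`CC2D`) averages 0.99 on both scenarios; the 6 df/year spline GLM is
attenuated to 0.67 and 0.57 — the smooth function of time cannot absorb the
shared 68–183-day periodicities, so they leak into the slope.  Each row is
an order statistic of the per-sample estimates (`Beta`) and their standard
errors (`SE`), one column pair per scenario.

The same machinery fits real daily counts:

```python
from ccwin import SeriesConfig, read_daily_csv, StratumScheme, ModelSpec, run_epi_analysis

cfg = SeriesConfig(column_map={"date": "date", "outcome": "cvd", "exposure": "o3",
                               "temperature": "temp"}, family="poisson")
series = read_daily_csv("chicago.csv", cfg)
result = run_epi_analysis(series, StratumScheme("CC2D"),
                          ModelSpec(family="poisson", temperature_spline_df=3), lag=1)
print(result.beta, result.ci95)
```

Other subcommands: `ccwin simulate` (write study sets), `ccwin fit` (one
series, one scheme, JSON result), `ccwin validate` (quick self-check).

## Documentation

See `docs/methods.md` for the statistical background, the simulator's
generative model and its defaults, numerical choices and known limitations.
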