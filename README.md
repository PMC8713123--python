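# expowin

Trailing exposure-window selection for ambient environment and binary health
outcomes, built around penalized-spline logistic additive models.

Given hourly weather/pollution station exports and a cohort table (one row
per participant with a recruitment date and a severity score), the pipeline:

1. **Ingests** hourly CSVs, drops records failing quality control, and
   averages to daily values (`expowin.ingest`).
2. **Imputes** missing days with a multivariate expectation–maximization
   model: per-variable cubic-spline time trends plus jointly Gaussian
   same-day residuals across variables (`em_spline_impute`).
3. **Builds exposures**: for each variable, the trailing mean over 0 (day of
   recruitment), 7, 15, 30, 60, 90, 120, 180, 270 and 365 days preceding
   each participant's recruitment date (`expowin.exposure`).
4. **Screens windows**: per variable, fits ten penalized logistic additive
   models (confounder base model + one smooth of the window column) and
   keeps the AIC-minimal window.
5. **Reduces collinearity**: variable pairs with |r| > 0.8 are merged into
   the first principal component of the standardized pair, iterated until
   all pairwise correlations are below the threshold.
6. **Selects a top model set**: backward drop-one-term search from the base
   model; all models fitted on the path form the candidate pool; the top set
   is every pool model within ΔAIC ≤ 6 of the minimum, then a nesting rule
   removes complex models that a strictly nested simpler candidate matches
   to within 2 AIC.  A second route fits one model with a double penalty
   (an extra penalty on each smooth's penalty null space) and reports terms
   whose effective degrees of freedom shrink below a threshold as removed.
7. **Evaluates**: a train/test surrogate experiment predicting the
   long-window ozone average from four driver averages, an external-cohort
   replication entry point sharing the same code path, and declarative
   sensitivity reruns.

A first-class synthetic-data module (`expowin.simulate`) generates
environment panels (annual seasonality, AR(1) serial correlation, an ozone
series structurally coupled to NO/humidity/wind/fine particulates, realistic
missingness) and cohorts whose outcome is driven by one known variable and
window, with the ground truth recorded — so window recovery and every
selection rule are testable.

## The GAM engine

`expowin.pgam` implements penalized-spline additive models from scratch:

- cubic B-spline bases on evenly spaced knots with order-2 difference
  penalties (P-splines); bivariate terms as tensor products with one penalty
  per margin; sum-to-zero constraints absorbed into each block;
- binomial (logit) and Gaussian families; penalized IRLS inner loop with
  step halving (penalized deviance is non-increasing);
- smoothing parameters by generalized Fellner–Schall updates of the
  (Laplace-approximate) restricted marginal likelihood, plus a discrete
  polish step for double-penalty fits;
- conditional AIC (−2·loglik + 2·EDF with EDF = trace of the influence
  matrix), adjusted deviance R², concordance index with stratified
  bootstrap CI, partial effects with pointwise 95% bands, odds-ratio tables,
  and prediction with intervals (extrapolation warns).

Passing `fixed_lambda=numpy.inf` fits the exact smoothing limit (each block
restricted to its penalty null space), which reproduces ordinary GLM/OLS
fits to machine precision.

## CLI

```bash
expowin simulate --preset single-window --seed 1 --out fixtures/sw
expowin ingest --weather weather.csv --aq aq.csv --out panel.csv
expowin impute --panel panel.csv --out panel_imputed.csv
expowin exposure --panel panel_imputed.csv --cohort cohort.csv --out exposure.csv
expowin screen --panel panel_imputed.csv --cohort cohort.csv --variable O3
expowin run --config run.yaml          # full pipeline, cached + hashed
expowin surrogate --panel panel_imputed.csv --split-date 2019-10-01
```

`run.yaml` holds every constant of the analysis (window list, collinearity
threshold 0.8, ΔAIC threshold 6, nesting tolerance 2, double-penalty EDF
threshold 0.05, bootstrap resamples, basis sizes, seeds); the resolved
config is written beside the outputs and reruns with identical inputs are
cache no-ops.

### Input dialects

Hourly exports (weather and air quality): CSV with columns

| column    | content                                              |
|-----------|------------------------------------------------------|
| timestamp | ISO-8601, hour resolution                            |
| variable  | `wind`, `humidity`, `temperature`, `NO`, `NO2`, `O3`, `PM10`, `PM2.5` |
| value     | numeric (weather units: mph / % / °C; pollutants µg/m³) |
| qc        | `pass`, `fail`, or empty (non-`pass` rows dropped and counted) |

Cohort CSV: `participant_id, recruitment_date, EASI, age, sex, BMI, lon,
lat, TEWL, SH, esec_class, investigator` (plus optional `season`,
`EASI10`).  Rows with out-of-area coordinates or missing
sex/TEWL/SH/ESeC/BMI are excluded with a per-reason tally.

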