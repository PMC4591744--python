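# Methods

This note documents the models implemented in `gfrmodels`, the assumptions
behind the synthetic-cohort simulator, and the numerical and design choices
made where the methodology leaves them open. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Study design emulated by the pipeline

The workflow mirrors a standard clinical prediction-model study: a combined
development + internal-validation cohort (default 414 records) is randomized
2:1 into a development set (276) used to fit equations and compute network
gradients, and an internal set (138) used exclusively for model selection
(network epoch snapshot and hidden-size choice). A temporally separate
external cohort (default 105) is reserved for the final comparison of all
fitted models against the published comparator equations. The development
count is `round(n · dev_fraction)` half-up; with arbitrary fractions both
arms are forced non-empty. Randomization is unstratified — nothing in the
design calls for stratification, and none is implied.

## Reference GFR and calibration

The reference ("standard") GFR is renal dynamic imaging GFR calibrated to
the dual plasma-sample Tc-99m-DTPA clearance by ordinary least squares:
`sGFR = intercept + slope · imaging GFR`. A built-in line
(3.706 + 1.039·x, R² 0.879, fitted on 36 subjects) ships for use when no
calibration pairs are available. OLS is used deliberately; errors-in-
variables alternatives (Deming, orthogonal regression) acknowledge noise in
the imaging measurement but are out of scope for this calibration step.

## Published equations

CKD-EPI creatinine, the Japanese equation, and its HbA1c-adjusted variant
are implemented exactly as printed, in mg/dL creatinine and
mL/min/1.73 m²; no body-surface-area re-normalization is applied. One
discrepancy is handled explicitly: some reprints of CKD-EPI give the
below-knot exponent α a *positive* sign (0.329 women / 0.411 men), which
would make eGFR increase with creatinine below the knot. The standard
negative-sign form is the default; `strict_printed=True` evaluates the
positive-α variant for auditability. The race factor (×1.159) is retained
for completeness but defaults to off, as the intended populations are
East-Asian cohorts. Creatinine files in µmol/L are converted with the
standard factor 88.4 µmol/L per mg/dL.

## New regression equations

`ln sGFR` is regressed by plain OLS (no selection or shrinkage) on

    1, min(ln(Scr/κ_sex), 0), max(ln(Scr/κ_sex), 0), age, [female], covariates…

with knots κ fixed at 0.7 (women) / 0.8 (men) mg/dL but configurable. The
min/max parameterization guarantees continuity in creatinine at the knot.
"Log scale" is taken as the natural logarithm throughout, matching the
CKD-EPI lineage. Eight covariate sets over {BMI, HbA1c, UACR} (none,
each singly, each pair, all three) define equations eq1–eq8; records
missing a required covariate fail loudly — nothing is imputed. Coefficient
standard errors come from the classical OLS covariance and serve
diagnostics only. By default coefficients are fitted on development-labelled
records; a `pool_internal` flag adds the internal set, since equation
fitting (unlike network selection) does not consume the internal set for
anything else.

A shape diagnostic fits per-sex cubic regression B-splines of `ln sGFR` on
`ln Scr`, with basis dimension chosen from a small grid by generalized
cross-validation. It exists to justify the two-slope approximation visually
and never enters prediction.

## GABP networks

Three-layer feed-forward networks: an input layer (age, female indicator
coded 1, creatinine, plus the variable set's covariates — 3–6 inputs), 1–11
logistic hidden neurons, and one linear output neuron. Inputs and output
are min-max scaled to [0, 1] on development data only, with the scaling
stored in the model; the linear output (the hidden layer uses the logistic
"S" function, the output activation being a free choice) is the standard
regression head and keeps the zero-weight network exactly at the scaled
midpoint. Training is full-batch gradient descent with momentum
(defaults lr 0.05, momentum 0.9, 2000 epochs, patience 200) on the
development MSE of the scaled output; the epoch snapshot with the lowest
internal-validation MSE is returned. Hidden-size search trains one network
per candidate size and keeps the internal-MSE argmin, ties going to fewer
neurons.

The genetic algorithm encodes all weights and thresholds of one network as
a real-valued chromosome (real coding avoids the precision artifacts of
binary coding). Generational replacement with elitism, fitness-rank
tournament selection, arithmetic crossover (rate 0.8) and per-gene Gaussian
mutation (rate 0.1) evolves the population; fitness is the
internal-validation MSE after `inner_training_epochs` of back-propagation
from the chromosome (0 = score the untrained network, which is the most
literal reading of selection "by performance in the internal validation
data-set"). The best chromosome ever seen initializes the final training
run. GA-per-size followed by size selection is one faithful composition of
the two searches; nesting them the other way is not implied by anything and
is not implemented.

### The initialization benchmark

`gabp_benchmark` quantifies the claimed benefit of GA initialization as a
paired experiment: for each of ≥20 independent synthetic problems
(noise-free targets generated by a random network of the benchmark
topology, hence exactly realizable), GABP (GA with untrained-chromosome
fitness, then 300 epochs of BP) is compared against one random draw from
the *same* initialization distribution (uniform ±2.5) trained for 300
epochs **plus** the GA's compute converted to epoch equivalents — a fitness
evaluation is one forward pass over the internal set, an epoch a
forward+backward pass over the development set plus an internal forward
pass. The benchmark runs at an aggressive full-batch learning rate (0.5),
the regime in which single random starts train unreliably and an
initialization optimizer earns its cost; at conservative rates with long
budgets, plain gradient descent converges from almost any start and the two
arms tie (or the plain arm wins on its extra epochs). A run whose loss
diverges scores infinite MSE. The reported comparison is the median
internal-validation MSE per arm and the fraction of seeds where GABP is at
least as good.

## Validation metrics

* bias = median of per-record differences, default sign eGFR − sGFR (an
  underestimating equation has negative bias); the convention is
  configurable because published tables are not always consistent about it.
* precision = Q3 − Q1 of the differences, with type-7 (linear
  interpolation) quantiles — the default convention of the major statistics
  environments; IQR values depend on it, so it is fixed and documented.
* P30 = percentage of estimates with |eGFR − sGFR|/sGFR ≤ 0.30; the 30 %
  boundary counts as within.
* 95 % CIs: percentile bootstrap over patients, 2000 resamples by default,
  seeded and reproducible.
* Paired model comparisons: Wilcoxon signed-rank on absolute errors
  (comparing |error| magnitudes is the standard reading of an accuracy
  comparison; zero differences dropped; exact null for ≤25 non-zero
  untied pairs, else normal approximation with continuity correction) and
  McNemar on the paired within-30 % indicators (exact two-sided binomial
  `min(1, 2·P(X ≤ min(b,c)))` for ≤25 discordant pairs, else chi-square
  with continuity correction). Two-sided tests throughout, α = 0.05, no
  multiplicity correction.
* Two-sample cohort comparisons route roughly symmetric variables (age,
  BMI, sGFR) to the t test and skewed labs (Scr, HbA1c, UACR) to the
  Mann-Whitney test, exact for small samples.

## Synthetic cohorts

The simulator draws sex ~ Bernoulli(0.543 male), age and BMI from truncated
normals (age ≥ 18 y, BMI > 0; means 59.8/25.0, SDs 13.1/3.5), and Scr,
HbA1c and UACR from log-normals — the natural family for right-skewed labs,
consistent with a UACR IQR (219 mg/g) several times its median
(42.6 mg/g). Log-normal parameters are matched to the target median m and
IQR via `sigma = asinh(IQR/(2m))/z₀.₇₅`, which reproduces both quartiles
exactly. Quartiles use the same type-7 convention as the metrics.
Covariates are independent by default; an optional Gaussian copula couples
them without changing any marginal (no joint structure is specified by the
summary statistics, so none is imposed by default).

The reference GFR is a configurable ground-truth model evaluated on each
record times `exp(ε)`, ε ~ N(0, noise_sigma²), default noise 0.2. The
default truth model is a two-slope spline with CKD-EPI-like slopes (−0.35
below, −1.2 above the knot), age decay ln 0.993 per year, female offset
ln 1.018, and intercept 4.81 placed so a typical subject (male, 60 y,
Scr 0.8 mg/dL) lands near the target population mean of ~81 mL/min/1.73 m².

What passing tests on these cohorts do and do not show: they verify the
machinery — exact coefficient recovery at zero noise, unbiased recovery
under noise, correct selection behaviour, metric and test-statistic
correctness — under a generating model that is itself a two-slope spline
with log-normal noise. Real diabetic cohorts have covariate correlations,
measurement-protocol artifacts, and creatinine–GFR relations that no
low-dimensional truth model captures; performance figures computed on
synthetic external sets characterize the toolkit, not any patient
population.

## Numerical choices and degenerate inputs

* OLS design rank is checked before fitting; constant spline columns
  (single creatinine value) or a constant female column (single-sex data)
  raise a collinearity error naming the columns.
* The logistic is evaluated with `expit` (overflow-safe); a training step
  that drives the loss non-finite raises a training error advising a
  smaller learning rate.
* Min-max scaling denominators of constant inputs fall back to 1 to avoid
  division by zero.
* Single-record summaries report SD 0; category bins are closed on the
  left, open on the right.
* All stochastic operations take explicit integer seeds (numpy
  `default_rng`); the CLI refuses stochastic subcommands without `--seed`
  unless `--no-seed` is passed. Fixed seeds give bit-identical model files
  and reports on a given platform.
* Model files are flat `key = value` text with `repr` floats, so
  round-trips are bit-exact and diffs are reviewable.

## Problem sizes

Default problem sizes throughout the tests and the acceptance script are
chosen to characterize each property at desk scale on one CPU: spline
recovery on 5000 records, OLS unbiasedness over 150 replicates of 600,
bootstrap coverage over 200 seeds × 2000 resamples at n = 500, the
initialization benchmark over 20–30 paired seeds, and the full pipeline at
the 414 + 105 study design with three candidate hidden sizes and a small GA
(population 12, 8 generations). Every one of these widths is a parameter,
not a constant.

## Known limitations

* The GA benefit is regime-dependent (see the benchmark section); the
  package makes no claim that GA initialization helps under every training
  configuration.
* No reproduction of externally fitted coefficients or trained network
  weights is attempted; fitted models here are compared against known
  synthetic generating mechanisms instead.
* Clinical exclusion criteria beyond the age/positivity invariants (edema,
  dialysis, drug interference) are not encodable from tabular data and are
  not modelled.
* Bias/precision/P30 are computed per cohort without multiplicity
  correction, matching standard practice in equation-validation tables.
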