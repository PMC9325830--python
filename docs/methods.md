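# Methods

## Model

The core regression treats the *absolute* absorbed dose A (µg/cm²,
receptor-fluid or potentially-absorbed endpoint) as a power-law function
of the applied dose D (µg/cm²), estimated linearly on decadic-log scale:

    log10(A) = β1 · log10(D) + β0 + ε,   ε ~ N(0, σ²).

The decadic logarithm is used throughout the user-facing scale (natural
logs appear only inside likelihoods); multiplicative (lognormal) error
is assumed, which matches percentage-scale data bounded away from zero
and the convention of fitting dose-group means. The competing
regulatory model regresses relative absorption (% of applied) on the
concentration of the test preparation, same transform.

Interpretation of β1: 1 = dose-proportional absorption (a single
relative value covers all doses); 0 = absorbed amount insensitive to
dose (the premise of concentration-based pro-rata extrapolation);
(0, 1) = less-than-dose-proportional; > 1 = smaller doses yield
disproportionately less absorption; < 0 = biologically implausible.

### Average dermal absorption

Fixing β1 = 1 reduces the intercept to the mean of the per-group
log-differences, β0 = mean(log10 A − log10 D), and

    DA_ave [%] = 10^β0 × 100

is exactly the geometric mean of the per-group relative absorption
percentages (property-tested as an identity). DA_ave is invariant to
rescaling all applied doses by a constant at fixed DA%. When the
companion free-slope fit has β1 > 1, `AverageDermalAbsorption` emits a
non-fatal warning: with β1 > 1 a slope-1 average under-predicts
absorption at high doses and a case-by-case assessment is indicated.
Concentrates and in-use dilutions have very different physico-chemical
behaviour and should never be pooled into one average; the study-table
API carries the preparation flag so callers stratify on it.

The free-slope analogue DA_rel|model = 10^β0 × 100 uses the fitted
intercept. Both back-transforms are computed at full floating
precision; rounding to 2 decimals happens only at report rendering.
(When a report is compared against hand calculations done on rounded
intermediate cells, totals can differ by one unit in the last place —
e.g. a column summing to 2.26 at full precision vs 2.27 from rounded
cells.)

## Estimation and numerical conventions

- **OLS** (`LogLogRegressor`): `scipy.stats.linregress` supplies slope
  and intercept; standard errors are computed from the residual sum of
  squares directly (robust where the correlation-based formula is
  undefined, e.g. constant response). Pairs with non-positive dose or
  absorption are excluded from log-scale fits with a per-record
  warning — zero recoveries are valid *data*, but have no log image;
  no floor substitution is applied by default because silently flooring
  would bias slopes.
- **Confidence intervals**: two-sided Wald t-intervals,
  β1 ± t(n−2, 1−α/2)·SE. Requires n ≥ 3.
- **AIC**: full Gaussian maximum likelihood, AIC = n·ln(2π·RSS/n) + n +
  2k with k = 3 (slope, intercept, residual variance) — the convention
  of R's `stats::AIC`, so values are comparable with analyses done in
  that lineage. RSS = 0 (up to float round-off, threshold 1e-27·n)
  returns −∞ as a sentinel rather than raising.
- **Mixed model** (`MixedLogLogRegressor`): statsmodels `MixedLM`,
  random intercept per product only — with 3–4 doses per product a
  random slope would be unidentifiable. Variance components by REML;
  the reported AIC comes from a parallel ML fit (k = 4) so it remains
  comparable across model forms. R² follows the Nakagawa decomposition:
  with σ²_f the variance (ddof = 1) of the fixed-effect predictions,
  σ²_u the random-intercept variance and σ²_e the residual variance,
  R²_marginal = σ²_f/(σ²_f+σ²_u+σ²_e) and R²_conditional adds σ²_u to
  the numerator. An exactly zero residual variance makes the mixed
  likelihood singular; callers with noiseless data should use the
  simple OLS (the estimates coincide as σ → 0).

### Comparing the dose form with the concentration form

`compare_model_forms` fits both forms on the same records and reports
slope, R² and AIC side by side, flagging that the responses differ
(log10 absolute absorbed vs log10 relative DA%), so the AIC comparison
is the conventional naive one without a Jacobian adjustment for the
response transformation.

One algebraic caveat is worth stating because it constrains what such a
comparison can show: if every record's applied dose is strictly
proportional to its concentration (a single fixed application volume),
then log10 DA% = log10 A − log10 D + 2 and subtracting the predictor
from the response leaves OLS residuals unchanged — the two forms are
exact reparameterisations with identical RSS and AIC. The forms only
separate when dose and concentration decouple (studies pooled across
different application volumes or test-item forms) *and* the true slope
differs from 1. The test suite asserts both regimes: the exact AIC tie
under coupling, and the dose-form AIC winning in ≥ 95 % of simulated
decoupled databases generated with slope 0.85 and a lognormal
application-volume spread (sd 0.8 log10 units).

## Slope classification

An 80 % two-sided CI supports four one-sided hypothesis screens at 95 %
confidence each. The partition, applied in order to a CI [lo, hi]
(closed intervals — a boundary touch counts as containment, the
conservative, more-compatible reading):

1. hi < 0 → **uncertain** (inverse dose–absorption relationship,
   biologically implausible; typically a stratum-corneum-residue
   artefact);
2. contains both 0 and 1 → **uncertain** (interval too wide);
3. contains 1 only → **1**;
4. contains 0 only → **0**;
5. lo > 1 → **> 1** (with a proximity note when lo ≤ 1.1);
6. otherwise → **0–1**.

Exactly one rule fires for every ordered interval (property-tested).
Note that published tabulations of the same scheme sometimes count
"0–1" and "1" non-disjointly; this partition is disjoint, so counts can
differ from such tables. Summary percentages are rounded half-up to
integers and may sum to 100 ± 2.

## Synthetic data generator

`GeneratorConfig`/`generate_study` emulate a multiple-concentration in
vitro study: each product is tested at ≥ 3 in-use dilution
concentrations (default 0.5/5/50 g a.i./L, spanning two orders of
magnitude, matching the ~4- to ~60-fold applied-dose ranges of real
multiple-concentration studies); the applied dose couples to
concentration through a fixed 10 µL/cm² application volume (1 g/L =
1 µg/µL, so D = volume × c); absorption follows the log–log line with a
Normal product random intercept (sd `tau_product`) and lognormal
residual (sd `sigma_resid` on log10 scale). Defaults `sigma_resid` =
0.2 and slope 1 around a few-percent absorption level are the package's
choice of a realistic regime — real study collections publish no
variance figures — and recovery simulations in the tests use
sigma 0.15–0.3. Draws whose relative recovery would exceed 100 % are
rejection-resampled (keeping log-scale Gaussianity approximately
intact, unlike truncation) with a logged counter; recoveries are
therefore always in (0, 100]. `generate_database` produces an
EFSA-database-like table (one dose group per product) and can decouple
dose from concentration via per-record volume jitter (uniform ±fraction)
or a lognormal volume spread.

What the generator does **not** emulate: co-formulant chemistry,
solubility-driven slope deviations of solid formulations, wash-in and
drying effects, replicate-level (per-donor) variation, or mass-balance
QC. Passing recovery tests on synthetic tables therefore demonstrates
the statistical machinery, not the behaviour of any real product class.

## Problem sizes

Simulation-based checks use: 2000 replicates for 95 % CI coverage
(4-dose studies, σ = 0.2); 200 replicates of 20 products × 4
concentrations for mixed-model slope recovery (median |error| ≤ 0.05);
25 replicates for variance-component recovery at test time; 50
two-stratum databases of 80 products each for the AIC-direction check.
These sizes give stable medians and proportions while keeping the suite
quick to run.

## Known limitations

- The package models dose-group *means*; weighting by replicate counts
  is not implemented.
- Logit-scale fits (nearly indistinguishable from log fits at small
  absorbed fractions) are not implemented.
- Flux/Fick's-law absorption metrics are out of scope; the method
  operates on cumulative recoveries as used in current regulatory
  practice.
- For in vivo records the "systemic dose" definition (blood vs excreta
  plus carcass) is whatever the data supplier used; the schema does not
  adjudicate it.
- The pro-rata comparator is capped at 100 %: the rule as practised is
  unbounded, but a relative absorption above 100 % is physically
  meaningless.
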