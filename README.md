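# dermabs

Log–log dose–absorption modelling for dermal absorption studies used in
non-dietary risk assessment of pesticides.

## The problem

In vitro dermal absorption studies (OECD TG 428) report the percentage
of an applied dose recovered in the receptor fluid of a diffusion cell —
the *relative* dermal absorption, DA_rel. European risk assessment ties
that percentage to the *concentration* of the tested spray dilution and,
when a use falls below the tested range, extrapolates it *pro rata*
(tested 1 % at 1 g/L → assumed 10 % at 0.1 g/L). That disconnects the
absorption estimate from the quantity that actually drives internal
exposure: the dose per cm² of skin.

`dermabs` implements the alternative: regress the absolute absorbed dose
A (µg/cm²) on the applied dose D (µg/cm²) on decadic-log scale,

```
log10(A) = β1 · log10(D) + β0
```

A slope β1 = 1 means absorption is directly dose-proportional, so a
single relative absorption value covers every exposure dose. Fixing the
slope at 1 makes model fitting redundant — the intercept is just the
mean log-difference — and back-transforms to a single **average dermal
absorption value**

```
β0 = mean(log10 A − log10 D),        DA_ave [%] = 10^β0 × 100,
```

which is algebraically the geometric mean of the per-dose-group DA_rel
values. The free-slope analogue is DA_rel|model = 10^β0 × 100 from the
fitted intercept. Fitted slopes are screened against the regulatory
hypotheses (β1 compatible with 0, with 1, strictly inside (0, 1), above
1, or undecidable) using confidence intervals — an 80 % two-sided
interval tests each one-sided hypothesis at the 95 % level.

The package provides:

- `study_data` — validated per-dose-group study tables (CSV I/O),
  receptor-fluid and potentially-absorbed-dose endpoints;
- `loglog` — `LogLogRegressor` (OLS on log10 scale, Wald t slope CIs,
  Gaussian-ML AIC with k = 3) and `MixedLogLogRegressor`
  (random-intercept-per-product, REML variance components, Nakagawa
  marginal/conditional R²), plus stratified fits and the dose-form vs
  concentration-form model comparison;
- `slopes` — the CI-based slope classification rule engine and its
  interpretive ledger;
- `averaging` — `AverageDermalAbsorption` (slope-1 DA_ave), model-based
  DA_rel, internal-dose prediction, the worked per-group report, and
  the pro-rata comparator;
- `toy` — the penetration-probability thought experiment bracketing the
  two regimes (slope 0 vs slope 1);
- `synthetic` — a seeded generator of study tables with the assumed
  statistical structure (dose coupled to concentration via a fixed
  application volume, lognormal residuals, product random intercepts);
- a `dermabs` command-line interface and an isoslope diagnostic plot.

Estimators follow scikit-learn conventions (`fit`/`predict`,
`get_params`, fitted attributes with trailing underscores) and compose
with sklearn tooling.

## Worked example

Three multiple-concentration studies with published per-dose-group
means, via the CLI (`dermabs fit study.csv`) or the library:

```python
>>> from dermabs import da_ave, fit_loglog
>>> groups = [(62.37, 5.2), (31.43, 8.93), (22.71, 12.54), (16.45, 13.96)]
>>> pairs = [(d, d * p / 100) for d, p in groups]     # (applied, absorbed)
>>> round(fit_loglog(pairs).slope, 3)
0.227
>>> est = da_ave(pairs)
>>> round(est.intercept, 2), round(est.value_pct, 2)
(-1.02, 9.5)
```

The fitted slope 0.227 says this product's absorption is far from
dose-proportional (relative absorption rises as the dose falls), yet a
single DA_ave of 9.50 % still covers it conservatively on the dose
scale. `dermabs fit` prints the full per-group report; the sum rows
show the conservatism direction — for this slope < 1 product the DA_ave
prediction (12.62 µg/cm² total) exceeds the observed absorbed total
(11.19 µg/cm²):

```
| product_id       | applied_dose | da_pct | absorbed_dose | ... | da_ave_pct | predicted_absorbed |
| FMC_P2_CS        |        62.37 |   5.2  |          3.24 | ... |       9.5  |               5.92 |
| FMC_P2_CS        |        31.43 |   8.93 |          2.81 | ... |       9.5  |               2.98 |
| FMC_P2_CS        |        22.71 |  12.54 |          2.85 | ... |       9.5  |               2.16 |
| FMC_P2_CS        |        16.45 |  13.96 |          2.3  | ... |       9.5  |               1.56 |
| FMC_P2_CS (sum)  |       132.96 |        |         11.19 | ... |            |              12.62 |
```

For the other two products in the bundled fixture the same pipeline
yields DA_ave = 1.46 % (slope 0.987) and 2.14 % (slope 1.56; a slope
above 1 triggers a case-by-case warning because a generic slope-1
average would under-predict at high doses).

The pro-rata comparator and the thought-experiment series:

```sh
$ dermabs pro-rata 1 1.0 0.1
10
$ dermabs toy
Case 1 (only the barrier-adjacent molecule penetrates):
  dose    1 molecules -> 100% relative absorption
  dose    2 molecules -> 50% relative absorption
  dose   10 molecules -> 10% relative absorption
  dose  100 molecules -> 1% relative absorption
Case 2 (every molecule penetrates with p = 0.1):
  dose   10 molecules -> 10% relative absorption
  ...
```

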