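# ccmort

Analysis toolkit for national childhood (0–14 years) cancer mortality
registries: direct age-standardisation, annual Poisson trends with
dispersion diagnostics and a joinpoint sensitivity scan, and — at its
core — detection of seasonality in monthly death counts. It was built
around the Hungarian childhood-cancer mortality record (2001–2021,
spanning the COVID-19 pandemic years) and ships the published monthly
summary tables as fixtures, together with a seeded synthetic registry
generator so the whole pipeline can be validated against a known truth.

## Who it is for

Epidemiologists and biostatisticians working with vital-registration
extracts: long-format tables of death counts by year, month, sex, age
group (0–4, 5–9, 10–14), NUTS2 region and cause group, plus annual
population denominators and monthly birth/death series.

## The statistics

**Seasonality (the core).** For twelve aggregated monthly counts
n₁…n₁₂ with mid-month angles θᵢ = 2π(i − ½)/12, the square-root
harmonic contrast is

    C = Σ √nᵢ cos(kθᵢ),  S = Σ √nᵢ sin(kθᵢ),  T = ⅔ (C² + S²)

which under the Poisson null is χ² with 2 df (Var √n ≈ ¼ and
Σcos² kθ = 6). k = 1 is Edwards' geometric single-peak test; k = 2
models two antipodal peaks six months apart; the Walter–Elwood variant
replaces √nᵢ with √nᵢ − √eᵢ where the expected counts eᵢ follow a
varying population at risk (with constant population it reduces exactly
to Edwards). The peak angle is atan2(S, C), the relative seasonal
excess α of the cosinor intensity 1 + α·cos(kθ − φ) is estimated by
4·√(C² + S²)/Σ√nᵢ. A harmonic Poisson regression
(log μᵢ = β₀ + offsetᵢ + Σₖ aₖcos kθᵢ + bₖsin kθᵢ) provides the
likelihood-ratio counterpart and supports proportionate-mortality
offsets; a multinomial Monte-Carlo calibration backs up the χ²
approximations at small counts.

**Trend.** log E[y_t] = β₀ + β₁(t − t₀) + log n_t; exp(β₁) is the
per-annum incidence rate ratio (IRR) with Wald 95% CI, an
equidispersion likelihood-ratio check against a negative-binomial
alternative (half-χ²₁ boundary correction), and a BIC scan for a single
slope change.

**Rates.** Crude and proportionate rates per 100,000 person-years with
Poisson/binomial SEs; direct standardisation over the child bands of
the Revised European Standard Population (weights 5000/5500/5500 per
100,000 for 0–4/5–9/10–14); two-sample z comparison of standardised
rates; male:female rate ratios with log-scale Wald CIs.

## Worked example

```python
from ccmort import load_fixture, edwards_test

table2 = load_fixture("table2")          # packaged monthly death counts
print(edwards_test(table2["2001-2010"]).summary())
```

```
Seasonality test: edwards (harmonic order 1)
  series         2001-2010  (N = 613)
  statistic      6.6118 on 2 df
  p (chi-square) 0.03667
  amplitude      0.147
  peak           Sep  (angle 255.6 deg)
```

The 613 childhood-cancer deaths of 2001–2010 show a significant single
seasonal peak (p ≈ 0.037) in September, with a ~15% peak excess over a
uniform month. The same data for 2011–2019 fit a double-peak
(second-harmonic) model with peaks in March and September (T = 8.28,
p ≈ 0.016), and the 66 pandemic-period deaths of 2020–2021 concentrate
sharply in January (T = 15.0, p ≈ 0.0006). The same analyses are
available from the shell:

```
$ ccmort season --fixture 2020-2021 --mc-reps 999 --seed 1
{
  "amplitude": 0.707,
  "label": "2020-2021",
  "method": "edwards",
  "order": 1,
  "p_chi2": 0.000552,
  "p_mc": 0.001,
  "peak_months": ["Jan"],
  "statistic": 15.005
}
```

Other subcommands: `ccmort trend` (annual IRR + joinpoint), `ccmort
rates` (direct ASMR), `ccmort simulate` (synthetic registry with a
manifest of true parameters), `ccmort report` (the full pipeline on a
registry extract, rendered as JSON/CSV/markdown).

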