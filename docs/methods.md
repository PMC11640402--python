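# Methods

This note records the models implemented in `ccmort`, the conventions
and numerical choices behind them, what the synthetic-data generator
does and does not emulate, and known limitations.

## Data model

A registry extract is a long-format table of cells
(year, month, sex, age group, region, cause) → death count, with
explicit marginal tokens (`all`, `0-14`, `HU`) so that national
summary tables — which publish only marginals — are representable.
Marginals are recomputable from strata and are cross-checked where both
are present. Aggregation over a study period uses calendar months; the
mean calendar length of each month over the period (leap-aware) is
carried alongside the counts for optional month-length adjustment.

### Monthly population estimation

Registries publish annual population figures but monthly death counts.
`estimate_monthly_population` treats the annual figures as population
stocks at the start of each January and advances a month-end stock
within the year by bookkeeping

    P_m = P_{m-1} + births_m − deaths_m − ageout,

where the age-out flow (children turning 15) is not observed and is
taken constant within the year, fixed by the residual that closes
December's stock onto the next annual anchor. The person-time
denominator for a month is the mid-month population, the mean of the
two adjacent month-end stocks, matching the mid-year convention used
for annual rates. With zero flows the scheme reduces to linear
interpolation between anchors, and the anchors are reproduced exactly
at year boundaries. Cohort-resolved interpolation by single year of
age would be an alternative reading; the stock formulation is the
simplest scheme consistent with the available inputs.

## Seasonality tests

### Angle convention

Month *i* (January = 1) is placed at the mid-month angle
θᵢ = 2π(i − ½)/12; harmonic order *k* multiplies the angles. These
angles are exactly balanced (Σcos kθ = Σsin kθ = 0, Σcos² kθ = 6 for
k ∈ {1, 2}), which makes uniform counts land exactly on the null
(T = 0) and gives the tests exact rotation equivariance: cyclically
shifting the count vector by j months shifts the peak angle by 2πj/12
and leaves the statistic unchanged. The symmetric mid-month placement
is also what maps the fixture columns onto their published peak months.
When converting a peak angle back to a calendar month, month *i* owns
the arc [2π(i−1)/12, 2πi/12), so an angle of zero is January.

### The square-root harmonic family

With sᵢ = √nᵢ, C = Σsᵢcos kθᵢ, S = Σsᵢsin kθᵢ, the statistic is
T = ⅔(C² + S²), referred to χ²₂: under a Poisson null Var(√n) ≈ ¼ and
the angle sums contribute the factor 6, giving variance 3/2 per
coordinate. Published algebraic variants of Edwards' statistic differ
by equivalent normalisations; the Monte-Carlo calibration (below) is
the arbiter of the approximation and agrees with χ²₂ to within ±0.01
on the packaged tables.

The Walter–Elwood form replaces sᵢ by the variance-stabilised residual
√nᵢ − √eᵢ with expected counts eᵢ = N·mᵢ/Σmⱼ proportional to the
population at risk mᵢ (optionally mᵢ·Dᵢ with month lengths Dᵢ).
Because the angles are balanced, constant mᵢ makes the √eᵢ term drop
out exactly and the test reduces to Edwards' — asserted to 1e−10 in the
suite. Amplitude and phase are read off the centroid: φ = atan2(S, C),
α̂ = 4·√(C² + S²)/Σ√nᵢ, estimating the relative excess of the cosinor
intensity 1 + α·cos(kθ − φ). For k = 2 the two peaks are constrained
antipodal (six months apart) by construction of the model.

The joint two-harmonic test adds the order-1 and order-2 statistics on
4 df and keeps the per-order components for model choice.

Month-length adjustment (rescaling counts to the mean month of
365.25/12 days, or weighting expected counts by Dᵢ) is off by default:
the unadjusted statistics are what reproduce the published peak months
from the printed counts, and the adjustment shifts T by well under one
unit on these data. A flag enables it.

Zero-count months contribute sᵢ = 0 without continuity correction.
Below 50 total events a `sparse` flag is set on results and reports
should prefer the Monte-Carlo p; the pandemic-period column (N = 66)
sits above this threshold but its χ² p agrees with the Monte-Carlo p to
three decimals anyway.

### Harmonic Poisson regression

log μᵢ = β₀ + offsetᵢ + Σₖ (aₖcos kθᵢ + bₖsin kθᵢ), K ∈ {1, 2}, fitted
by IRLS (statsmodels GLM). The seasonality test is the likelihood ratio
against the intercept-only model on 2K df; goodness of fit is the
residual deviance on 12 − 1 − 2K df. The offset carries log
person-time, or the log of a reference count series for proportionate
analyses (e.g. all-cause deaths). Near significance its p-values track
the square-root harmonic test closely (within 0.02 on the packaged
columns); far from significance the two approximations can differ by
more while agreeing in conclusion.

A caveat on proportionate analyses of the packaged data: only the
pooled 2001–2021 all-cause monthly column is published, so a
proportionate analysis of a sub-period must borrow the pooled profile
as its offset. That profile is nearly uniform, so the proportionate
p-values track the unadjusted ones; sub-period-specific all-cause
denominators, which are not public, could move them.

### Monte-Carlo calibration

Conditional on the total N, the null hypothesis distributes deaths
multinomially over months with probabilities proportional to the
population at risk (uniform when none is attached; month lengths enter
when the statistic adjusts for them). The p-value is
(1 + #{T\* ≥ T})/(B + 1) with B = 9999 by default in reports; it is
exactly reproducible for a fixed seed. Under the uniform null with
N = 600 the χ² tests' empirical size at α = 0.05 is within [0.03,
0.07] for both orders (2000-replicate check in the suite).

## Annual trend

Poisson GLM with log person-time offset, year centred at the first
study year (the IRR is invariant to centring; convergence tolerance
1e−10). Wald 95% CIs on the log scale. Two support points fit the
saturated model exactly; reversing the time axis inverts the IRR.

**Equidispersion.** The Poisson assumption is checked by a likelihood
ratio against a negative-binomial (gamma-mixture, quadratic-variance)
alternative with one extra parameter. The dispersion parameter lies on
the boundary under the null, so p = ½·P(χ²₁ ≥ LR). The boundary
correction makes the test conservative (empirical size ~2–5% at these
data sizes) and it retains ≥80% power against variance five times the
mean at ~1000 total events.

**Joinpoint scan.** Continuous piecewise log-linear Poisson models with
a hinge max(t − c, 0) at every interior candidate year (at least three
years per segment), selected by BIC against the single-segment model.
The BIC of a joinpoint model charges four parameters — intercept,
slope, slope change, and the searched breakpoint location; charging
only the three regression coefficients lets the maximum over ~15
candidates masquerade as a single pre-specified test and drops null
specificity to ~70%, whereas the four-parameter charge keeps
zero-joinpoint selection above 90% on log-linear series while locating
a genuine IRR 1.00 → 0.90 slope change to within ±2 years essentially
always. This is a sensitivity analysis; it is not the grid-search
permutation procedure of the NCI Joinpoint program.

Age-group trend effects, where used, enter as an ordinal per-group
increment (a single IRR per step across 0–4 → 5–9 → 10–14), which is
one of two readings of a jointly reported "older age groups" effect;
categorical coding is the alternative.

## Rates and standardisation

Direct standardisation uses the child bands of the Revised European
Standard Population (ESP-2013): 5000, 5500, 5500 per 100,000 for 0–4
(1000 for age 0 plus 4000 for 1–4), 5–9 and 10–14, normalised over the
three groups. The SE of the standardised rate is the Poisson delta
method, 100000·√(Σ w̃²ₐ dₐ/n²ₐ). Period person-time is the sum over
years of mid-year populations (additive, equivalent to average
population × years up to rounding). Two standardised rates are
compared by a normal z-test on the standardised scale. The
male:female ratio uses the log-scale Wald CI
exp(log R ± 1.96·√(1/d₁ + 1/d₂)).

## Synthetic registry generator

The generator draws Poisson monthly counts with intensity

    λ = person-years(y, m)/10⁵ · r₀ · g^(y−y₀)
        · (1 + α₁cos(θ_m − φ₁) + α₂cos(2θ_m − φ₂)) · multipliers,

person-years(y, m) = mid-month population × actual calendar days/365.25.
Defaults are the study conditions: r₀ = 4.3 per 100,000 person-years at
2001, g = 0.976 per annum, a child population declining linearly from
1.65 million by 12,000 per year. Stratification uses fixed population
shares and relative-risk multipliers per sex, age band and region
(boys ~27% higher risk; risk declining with age; the two north-eastern
regions elevated), with the multipliers' population-weighted means ≈ 1
so the national rate tracks r₀. Seasonal "regimes" may switch over
time; `emulate_paper_scenario` uses three — a single September peak
(α₁ = 0.30) for 2001–2010, an antipodal March/September pair
(α₂ = 0.35) for 2011–2019, and a strong January peak (α₁ = 0.70) with
an 0.85 rate multiplier for 2020–2021 — calibrated so expected period
totals sit near 613/413/66 deaths and each period's test has high power
at its realised size. The regime amplitudes are deliberately somewhat
above the point estimates the printed counts give (0.15/0.20/0.71), at
the detectability edge for totals this small.

Randomness is split into per-stratum substreams keyed by a stable hash
of the stratum label, so changing one stratum's parameters (or adding a
stratum) never perturbs another stratum's draws. An overdispersion
knob gamma-mixes the intensity (variance multiplier 1 + v·λ) to
exercise the dispersion diagnostic; the default is pure Poisson,
consistent with the equidispersion finding on the real series. The
population trajectory is emitted both as truth and as
anchors-plus-flows, so the monthly population estimator round-trips it
exactly.

What the generator does **not** emulate: individual-level records,
cause-of-death miscoding, within-stratum correlation of counts beyond
the shared intensity, migration or age-structure shifts in the
population, and reporting delays. Passing tests on synthetic data
therefore demonstrate correctness of the estimators under the stated
model, not robustness to those real-data features.

## Problem sizes used in validation

Simulation-based checks in the suite use 100–200 replicates (CI
coverage of the IRR, peak-month recovery, joinpoint selection rates),
2000 replicates for the size calibration of the harmonic tests, and
B = 4999–9999 Monte-Carlo resamples on the fixture columns; these sizes
put Monte-Carlo error comfortably inside the asserted bands.

## Known limitations

* The published monthly population at risk is not available, so the
  population-at-risk tests on the packaged tables run with a constant
  denominator and reduce to the geometric test; the resulting p-values
  differ from the originally published ones in the third decimal
  (0.037 vs 0.039 for 2001–2010; 0.016 vs 0.014 for 2011–2019).
* The display convention "rates to 2 dp, p to 2–3 decimals, <0.001
  floor" matches epidemiological tables; exact machine values are
  always retained in JSON output.
* No multiplicity adjustment is applied across periods or harmonic
  orders, matching common practice in descriptive seasonality analyses;
  the joint 4-df test is provided as the conservative alternative.
* Joinpoint inference is model selection, not hypothesis testing; the
  reported breakpoint has no CI.
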