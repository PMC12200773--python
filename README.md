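# droughtlink

Characterise drought exposure from gridded SPEI series and estimate its
association with a recent binary outcome in multi-country survey microdata,
using a varying-intercept Bayesian logistic regression.

## The problem

Climate stressors plausibly shape the risk of interpersonal violence against
adolescent girls and young women in low- and middle-income countries, but
linking the two requires (i) turning a monthly drought index into
epidemiologically meaningful exposure categories over the years preceding
each survey interview, (ii) attaching grid-cell climate to survey respondents
known only by census district, and (iii) a model that pools 10–20 countries
while respecting between-country heterogeneity. `droughtlink` implements that
pipeline for researchers working with georeferenced household surveys and the
Standardized Precipitation-Evapotranspiration Index (SPEI), and ships a
synthetic-data generator that stands in for the restricted survey microdata,
so every stage can be validated against known ground truth.

## Drought characterisation

A month is **dry** when SPEI ≤ −1. On maximal runs of consecutive dry months,
two independent drought definitions apply:

* **count method** (duration): runs of ≥ 5 consecutive dry months;
* **sum method** (intensity): runs whose summed SPEI is ≤ −17.5.

Each qualifying run is one **drought cycle**. Months satisfying both methods
form the *both* measure. The **standardized dryness intensity** is

```
sdi = (Σ SPEI over sum-method cycles) / (drought months per cycle)
    = S / (n_sum / k),     S = Σ sums, k = number of sum-method cycles
```

Over the 48-month window ending the month before each interview, four
(possibly overlapping) exposure categories are derived:

| category | rule |
|---|---|
| slight to moderate | ≥ 1 month with −1 < SPEI < 0 |
| very dry | sdi in the most-negative decile across the sample |
| recent and long | a dry run of > 12 months within the trailing 24 |
| prolonged and extreme | both-months count in the top decile (and > 0) |

Cell-level measures are averaged to districts with coverage weights; the
decile thresholds are computed across district-window units after
aggregation.

## Association model

One model per exposure category (reference group: everyone else):

```
y_i ~ Bernoulli(p_i),  logit p_i = a_{c[i]} + β·x_i + γ₁ age + γ₂ school + γ₃ partnered + γ₄ poor
a_c ~ Normal(μ, σ²),   β, γ, μ ~ Normal(0, 1),   σ ~ Half-Normal(1)
```

sampled with an in-package Hamiltonian Monte Carlo sampler (dual-averaging
step-size adaptation, diagonal mass matrix, centred or non-centred country
intercepts chosen per dataset). Summaries report the posterior mean
(Estimate), SD (SE), OR = exp(Estimate), and the 95% credible interval from
the 2.5/97.5 posterior quantiles, gated on split-R̂ ≤ 1.01 and bulk
ESS ≥ 400. Survey-weighted prevalence with linearised SEs is computed per
country.

## Worked example

```sh
python analysis/01_simulate.py --seed 1 --out-dir results
python analysis/02_exposure.py --out-dir results
python analysis/03_link.py     --out-dir results
python analysis/04_fit.py      --seed 1 --out-dir results
python analysis/05_report.py   --seed 1 --out-dir results
```

The first three steps print, for a 48-cell grid and a 6,000-respondent
cohort:

```
raw recent-outcome rate: 0.082; lifetime rate: 0.195
35.4% of cell-windows contain months meeting both drought criteria; mean dry months 10.9/48
linked 6000 respondents (0 rejected)
category thresholds: sdi <= -2.996140089772301, both-months >= 13.249999999999998
  slight_to_moderate     exposed   5010 (exclusively 3707)
  very_dry               exposed    522 (exclusively 0)
  recent_and_long        exposed    265 (exclusively 0)
  prolonged_extreme      exposed    781 (exclusively 0)
```

i.e. mild dryness touches most districts while the extreme categories mark
the tail, overlapping each other as expected. The fit step then prints one
row per category — posterior mean log-odds, OR and 95% credible interval:

```
slight_to_moderate     estimate -0.087 OR 0.917 [0.700, 1.218] (centered, converged)
very_dry               estimate +0.112 OR 1.119 [0.778, 1.585] (centered, converged)
recent_and_long        estimate -0.593 OR 0.553 [0.254, 1.120] (centered, converged)
prolonged_extreme      estimate +0.025 OR 1.025 [0.765, 1.357] (centered, converged)
```

At this small demonstration size the intervals are wide; the credible
intervals cover the generating coefficients, and parameter recovery at
n = 20,000 (see below) pins the exposure effect to within a few hundredths.
The report step writes `report.json` / `report.txt` with diagnostics,
posterior predictive summaries and dropped-row accounting.

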