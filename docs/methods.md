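# Methods

## The problem

Conventional burden-of-disease accounting (DALYs) measures how sick a
population is, but not *why* the burden persists: how much has already been
removed by existing treatments, how much more could be removed if people
used and could afford those treatments, and how much would remain until a
new technology eliminates the disease. `unmetneed` decomposes the morbidity
part of burden into exactly those pieces for five index conditions
(rheumatoid arthritis, breast cancer, Parkinson's disease, hepatitis C,
COPD) in two regions (US, EU5 = UK + Germany + France + Italy + Spain,
pooled without country effects).

## The utility regression

Each survey respondent carries an SF-6D utility score `u ∈ (−1, 1]`
(1 = perfect health; values below 0 are states worse than death; disutility
is `1 − u`). We fit, by ordinary least squares and separately per region,

```
u = β₀ + Σ_a β_a·age_a + β_m·male + Σ_k β_k·comorbid_k
    + Σ_d γ_d·cond_d + Σ_j δ_j·access_j + Σ_d Σ_j θ_dj·cond_d·access_j + ε
```

with dummies for age group (reference 18–34), gender (reference female) and
comorbidity class (0 / 1 / 2 / 3+, reference 0), indicators `cond_d` for the
five conditions, and five access/utilization terms `access_j`: two adherence
dummies (low/medium and high, against "not using medications" — the MMAS-8
dichotomy high vs. low/medium plus a non-user state), the two cost-barrier
indicators, and physician attentiveness. With all five conditions and
interactions the design has 43 terms. `γ_d` is the adjusted disutility of
condition *d* for an untreated-access profile; `δ_j + θ_dj` is how access
moves utility for patients with condition *d*.

Design choices that were genuinely open:

* **Access main effects for everyone.** The access terms enter for all
  respondents, not only those with an index condition; otherwise the
  interactions are uninterpretable against the reference.
* **Adherence is per respondent**, not per condition; multi-condition
  respondents share one adherence state (they are rare at realistic
  prevalences).
* **Regions are fit separately** rather than pooled with region
  interactions, so every coefficient (including residual variance) is free
  to differ across health systems.
* **No truncation of predictions.** Fitted values may exceed 1; a reporting
  flag (`clamp`) caps them, but nothing in the estimation path clamps.
* **Rank deficiency raises** (naming the collinear columns — typically a
  condition with no variation in an access variable) rather than silently
  dropping terms.
* An optional per-row `weight` column switches the fit to weighted least
  squares; the core makes no use of survey weights otherwise.
* Coefficient covariance is the classical `σ̂²(XᵀX)⁻¹`; the OLS/WLS
  computation is delegated to statsmodels behind this module's interface.

## Counterfactual scenarios and the decomposition

For each condition, utility is re-predicted for the respondents who have it
("recycled predictions") under four scenarios:

| scenario | adherence | cost barriers | attentive doctor | condition flag |
|---|---|---|---|---|
| observed | as reported | as reported | as reported | as reported |
| worst | low/medium | both present | no | kept |
| optimal | high | none | yes | kept |
| no_disease_optimal | high | none | yes | removed |

The worst scenario uses low/medium adherence rather than "not using"
because non-use empirically proxies for *mild* disease, not absent care; a
switch (`worst_adherence="not_using"`) flips this interpretation.

Scenario means within age × gender strata (and overall) yield the additive
decomposition of total need `1 − U_worst`:

* **met need** `U_observed − U_worst` — burden already removed by current
  technologies;
* **unmet need, ineffective use** `U_optimal − U_observed` — removable by
  better access to and use of what exists;
* **unmet need, lack of technologies** `U_no_disease − U_optimal` — removable
  only by eliminating the disease;
* **comorbidity residual** `1 − U_no_disease` — would remain even then.

Additivity is definitional and asserted at 1e−10. Components are reported
as-is, including negative values that arise when a fitted interaction has a
"wrong" sign; no flooring. Monotonicity of the scenario means
(worst ≤ observed ≤ optimal ≤ no-disease) is guaranteed pointwise only when
the access effects carry their expected signs, so tests assert it for the
data-generating coefficients, never for arbitrary refits. A separate
reporting quantity, the *adjusted disease disutility*, removes the condition
while leaving access at observed values — the utility the condition itself
costs patients under current care.

Strata are averaged with raw respondent counts (no survey weights), and a
respondent with several index conditions contributes to each condition's
analysis; the no-disease scenario removes only the target condition.

## YLD and prevalence

`YLD(a,g,c) = DW(a,g,c) · p(a,g,c)`: each stratum's disutility-weight
component multiplied by the prevalent case count from a GBD Results Tool
export (metric **Number**; a rate-based mode is deliberately not provided,
since absolute person-years are the decision-relevant output). GBD
five-year bands are collapsed by summation into the survey bands at the
35/55/75 boundaries; a band straddling a boundary raises rather than being
prorated, 15–19 is assigned to 18–34 with a logged caveat, and bands
entirely below 15 are skipped. The five EU5 countries are summed into one
region. Stratum-specific (not condition-average) disutility weights
multiply stratum prevalence. GBD upper/lower prevalence bounds are read but
not propagated into intervals.

## Simulation-based intervals

Coefficient vectors are drawn from the asymptotic normal
`N(β̂, Σ̂)` (default 1000 draws; Cholesky factorization with a 1e−10 ridge
fallback for numerically singular Σ̂, an exact shortcut for an all-zero Σ̂).
Every derived quantity here — scenario means, decomposition components,
adjusted disutilities, YLD cells — is linear in β for a fixed sample, so
each is evaluated as `w·β` across draws; arbitrary callables are supported
for non-linear functionals. Point estimate and 95% bounds are the mean and
the empirical 2.5/97.5 percentiles with linear interpolation between order
statistics (numpy's default). Only coefficient uncertainty is simulated;
prevalence and sampling-design uncertainty are not.

## The synthetic generator

Real multi-country health-and-wellness survey microdata are proprietary, so
the `survey` module generates tables with the same variable structure:
covariates drawn independently from configured marginals, utility generated
from the same linear model the estimator fits plus Gaussian noise
(`noise_sd` default 0.15, about the residual scale of SF-6D regressions),
then clipped to [−1, 1].

Defaults (one region per call, default US): age 26/35/34/5% across
18–34/35–54/55–74/75+; gender 52/48 female/male; comorbidity classes
35/20/15/31%; cost-prevented 23%, cost-cutting 41%, attentive doctor 91%;
adherence 40/35/25% not-using/low-medium/high, optionally overridable per
condition; condition prevalences 1.0/1.5/0.4/0.8/2.0% (RA/breast
cancer/Parkinson's/hepatitis C/COPD) — plausible adult fractions. The
default "truth" coefficients carry the signs such studies report: condition
effects −0.05 to −0.12, utility falling with comorbidity count, negative
cost-barrier effects, positive high-adherence and attentiveness effects
(main and interaction), intercept 0.80.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: correlated covariates (e.g. comorbidity
rising with age, adherence depending on costs), within-respondent
correlation of condition flags, non-Gaussian and heteroskedastic utility
errors, ceiling pile-up at 1, selection and recall bias of self-reported
online surveys, and any causal confounding of the access variables. Tests
against it verify the estimator and pipeline arithmetic, not the
substantive conclusions one would draw from a real survey.

One subtlety: the ceiling clip at 1 (`truncate_utility`, default on) makes
the generator realistic but the OLS estimand no longer exactly the generator
coefficients. Recovery, coverage, and coverage-of-interval studies therefore
disable truncation — they test the estimator under its own linear-Gaussian
model; with the default predictor scale (≈0.8) and noise 0.15 the clip would
otherwise bias the intercept by roughly −0.01.

## Problem sizes and numerical conventions

Statistical test studies use n = 50,000 respondents × 200 replicates for
coefficient recovery (coverage asserted within 95% ± 4 points per
coefficient, |bias| ≤ 0.005) and n = 20,000 × 200 datasets for interval
coverage — sizes at which every condition × access interaction cell is
reliably populated at the default prevalences. The demonstration pipeline
(`scripts/acceptance.py`) uses n = 20,000 per region and 1000 coefficient
draws. Oracle comparisons use explicit normal equations `(XᵀX)⁻¹Xᵀy` at
1e−10, exact identification at 1e−8, additivity at 1e−10, aggregation at
1e−9 relative. Ties/degenerate inputs: zero covariance short-circuits to
point-mass draws; empty tables are valid for I/O but rejected for fitting;
rows with missing modeled fields are dropped on read with a logged count.

## Known limitations

Cross-sectional data cannot support the causal reading of the scenario
gaps; access effects are treated as causal by assumption. Mortality (YLL)
is out of scope, so conditions with high fatality (e.g. breast cancer) are
understated relative to a full DALY. Only three drivers of achievable unmet
need are modeled (financial barriers, perceived quality, adherence);
omitted drivers (geographic access, regulatory availability, unperceived
quality problems) would shift burden from "lack of technologies" toward
"ineffective use". Negative decomposition components are possible and are
reported unmodified.
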