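# Methods

`pmcox` implements the analysis machinery of large administrative-cohort
studies of long-term fine-particle (PM₂.₅) exposure and cause-specific
mortality: stratified Cox proportional-hazards models fit on person-months,
made tractable at scale by exact sufficient-statistic grouping, together
with spline exposure-response estimation, interaction-based effect
modification, a two-stage "non-traffic PM₂.₅" decomposition, and a
synthetic-cohort generator that supplies ground truth.

## The hazard model

The unit of analysis is the **person-month**: one row per beneficiary per
month at risk, on a follow-up time axis t = months since cohort entry
(entry = the later of the study start and the month the person becomes
eligible). The hazard for cause c is

    λ_ic(t) = λ0_{s(i,t),c}(t) · exp(βc' x_i(t))

where the stratum s = (attained-age bin × sex × race × ZIP [× SES tertile])
indexes a completely unrestricted baseline hazard, and x_i(t) contains the
time-varying exposure terms (trailing 12-month mean PM₂.₅, spline basis
columns, interaction columns, adjustment covariates). Attained-age bins are
one-year bins 65…89 plus a single open 90+ bin, so the stratum of a person
changes as they age. Deaths from causes outside c censor at the death month
(cause-specific hazard convention); administrative censoring occurs at the
study window's end.

**Why follow-up time, not calendar time.** With ZIP and age inside the
strata and exposures defined per ZIP-month, a calendar-time axis would put
every member of a risk set in the same calendar month — and hence give them
identical exposure, leaving no within-risk-set contrast anywhere. On the
follow-up axis, people who entered in different calendar months occupy the
same risk set with different exposure histories, which is what identifies
the coefficient. Identification therefore comes from staggered entry and
from residential moves; both are real features of an open administrative
cohort, and both are simulated.

## Grouped sufficient statistics and Breslow ties

At monthly resolution, ties are not an edge case: every death in a stratum-
month is tied with every other. The Breslow approximation treats all events
at one (stratum, time) as sharing a single risk-set denominator, which makes
the partial likelihood a function of *grouped* data only. Person-months are
compressed into cells keyed by (stratum, follow-up month, covariate
vector), each carrying an at-risk count w and an event count e. For a risk
set R(s,t) with d = Σ e events,

    ℓ(β) = Σ_{s,t} [ Σ_{cells} e·β'x − d · log Σ_{cells} w·exp(β'x) ]

with gradient and observed information accumulated from the weighted first
and second moments of x within each risk set. The compression is **exact**,
not an approximation — the test suite verifies value, gradient and
information against the uncompressed evaluation to 1e-8 — and risk sets
with no events contribute identically zero and are dropped. Cell keys use
exact covariate values by default (ZIP-month exposures are already shared
across many people); an optional fixed-decimal rounding coarsens the key
for workloads where that matters. Compression is modest in the synthetic
worlds here (fine strata, many distinct exposure values) and grows with
cohort density per ZIP.

Exponentials are guarded with a per-risk-set log-sum-exp shift. All
reductions (`reduceat` over a deterministically sorted cell order, explicit
column-wise accumulation for the linear predictor) are fixed-order, so the
same inputs produce bit-identical results regardless of threading or
execution order. The log-likelihood convention matches R
`survival::coxph(ties="breslow")` exactly (no tie-factorial constant);
`lifelines`' time-varying fitter uses Efron ties and therefore only agrees
when risk sets happen to be tie-free.

## Optimization

Newton–Raphson with step-halving (at most 10 halvings per step), starting
from β = 0. Convergence requires the relative log-likelihood change to fall
below `tol` (default 1e-8) — conservative defaults chosen for
reproducibility rather than speed; fits at the sizes used here take 3–5
iterations. The covariance is the inverse observed information at β̂.
Two pathologies are detected rather than silently returned: a singular
information matrix raises a rank-deficiency error naming the aliased
covariates (via the eigen-null-space), and a monotone likelihood (e.g.
perfect separation) is flagged when any |β_j| times the covariate
half-range exceeds 20 — a linear-predictor spread no real hazard ratio
produces — or when the information collapses along the divergence
direction mid-path. RR computations refuse unconverged fits.

## Exposure handling

* **Grid matching** — beneficiaries are matched to the surface location
  nearest their ZIP centroid by great-circle (haversine) distance; distance
  ties break to the smaller location id.
* **12-month average** — the time-varying exposure at month t is the mean
  of months t−11…t (the current month included), evaluated along the
  person's own residence path so windows crossing a move mix the two ZIPs'
  series month by month. Months before the first recorded residence use the
  entry ZIP. A window with any missing month yields a missing covariate;
  such person-months are excluded from the risk set and counted, never
  imputed.
* **Warm-season ozone** — April–September mean of daily 1-h maxima per
  year; more than 25% missing days signals missingness. When ozone arrives
  as monthly means, the season average weights months by day count. Ozone-
  adjusted models are restricted to ZIPs within 6 miles of a monitor.
* **Low-exposure restriction** — ZIPs with study-period mean strictly below
  8, 10 or 12 µg/m³; a beneficiary is retained when every ZIP in their
  residence history is retained, so the retained cohorts nest across
  thresholds.
* **Two-stage non-traffic PM₂.₅** — stage 1 is pooled OLS of 12-month
  PM₂.₅ on 12-month NO₂ over ZIP-months (a single pooled fit keeps the
  residual on one interpretable scale; a per-ZIP variant would give each
  ZIP its own zero point). The fitted line is applied to person-level
  (PM₂.₅, NO₂) pairs, and the residual is the stage-2 exposure. Residuals
  are exactly orthogonal to NO₂ over the fitting sample. Because the
  residual removes a *noisy proxy* of traffic PM₂.₅, stage-2 estimates
  carry extra measurement noise and wider CIs — visible in the attenuation
  experiments.

## Splines and effect modification

Restricted cubic splines use the truncated-power form with m ∈ {3,4,5}
knots, normalized by (k_m−k₁)² so every column shares the exposure's units;
m−1 basis terms, b₁(x) = x. Tails are linear beyond the boundary knots,
which makes the curve's 0 µg/m³ reference a well-defined extrapolation even
though 0 lies below all observed exposures (this is explicit, documented
extrapolation). Knots default to quantiles of the person-month exposure
distribution — (10, 50, 90)% for m=3, (5, 35, 65, 95)% for m=4,
(5, 27.5, 50, 72.5, 95)% for m=5 — because the likelihood weights
person-months, not beneficiaries. Candidate knot counts are compared by AIC
on the partial likelihood (2k − 2ℓ̂), ties resolving to fewer knots; the
criterion is a package choice, made because "performance" admits several
readings and AIC is the conventional one for partial likelihoods. RR
curves are reported with delta-method pointwise 95% CIs and are invariant
to basis rescaling (verified at the curve level, since truncated-power
parameterizations differ across conventions).

Effect modification uses a single joint fit with exposure × level
interaction columns for each non-reference level; the modifier's main
effects are absorbed by the strata (every supported modifier — age group,
sex, race, urbanicity, SES tertile — is a stratum dimension or constant
within one). Level RRs are exp(10(β + γ_level)) with covariance-propagated
CIs. Levels with no events, or whose events all sit in contrast-free risk
sets (aliased interaction column), are reported as inestimable rather than
failing the fit. No multiplicity correction is applied — subgroup tables
mirror the single-comparison presentation standard in this literature.

SES enters either as a fifth stratum dimension (default) or as an ordinal
covariate, switchable in the run configuration, since both adjustment
styles are common. SES tertiles cut the per-ZIP annual income distribution
at its 1/3 and 2/3 quantiles, recomputed per calendar year, boundary values
falling to the lower tertile (deterministic and order-invariant); the
missing 2000 and 2003 survey years are carried from 2001 and 2004.

ICD-10 causes are grouped by three-character category root; subcodes
inherit the root's mapping, and ranges compare lexicographically. The
"cancer C–D" block is bounded at D48 (the neoplasms chapter) — a literal
C00–D99 would sweep in blood diseases. The shipped map is editable config.

## The synthetic generator

The generator emulates the *structure* of a national elderly-mortality
study: an open cohort (default 50k beneficiaries across 500 ZIPs over
2000–2008; 60% enrolled at the window start, the rest aging or migrating
in), ZIP-level exposure surfaces, and monthly cause-specific deaths from
the exact hazard model above, with every planted parameter emitted in a
truth sidecar. Monthly death indicators are Bernoulli(1−exp(−h)); at
monthly hazards of ~0.001–0.01 this agrees with the continuous-time model
to first order, and the recovery tests bound any residual gap empirically.

PM₂.₅ is the sum of a traffic and a secondary (non-traffic) component.
Component means are urbanicity-dependent — the urban excess (11.2 vs 8.0
µg/m³) is traffic-driven, while the secondary mean is spatially flat, as
regional pollutants are — with lognormal-scale ZIP variation, a seasonal
cycle on the secondary component, and highly persistent AR(1) monthly noise
(ρ=0.97), because slow multi-year drifts are what survive 12-month
averaging. NO₂ is affine in the traffic component plus autocorrelated
noise whose scale is solved in closed form from the realized component
moments so that corr(12-mo PM₂.₅, NO₂) hits its 0.59 target (ozone couples
to the secondary component the same way, target 0.24). A finite-ZIP draw
occasionally leaves the traffic component short of the variance the target
requires; such worlds are rejected and redrawn deterministically (bounded
retries), and a structurally unattainable target raises a calibration
error. EC-like and sulfate-like annual tracers are proportional to the
traffic and secondary components plus noise.

Default planted RRs per 10 µg/m³ are the magnitudes this literature
reports for the elderly (e.g. 1.126 IHD, 1.126 CBV, 0.986 CHF, 1.023 COPD,
1.078 pneumonia, 0.995 lung cancer, 0.998 accidental), with baseline
mortality following a Gompertz-like age gradient (0.0011/month at 65,
log-slope 0.09/year, male excess 1.35) and a death-cause mix matching the
familiar shares (40% CVD, 11% respiratory, 22.5% cancer). ICD codes are
drawn uniformly over each cause's category roots. Optional planted
structure includes subgroup multipliers (default: Black beneficiaries
+0.056 on the log-RR scale), a slope change at a threshold, and a
traffic-weighted effect for two-stage experiments.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: real geography and spatial autocorrelation
(ZIPs are exchangeable points), exposure prediction-model error,
confounding (SES affects nothing in the default world, so "adjusted" and
"base" models differ only by noise), cause-of-death miscoding, seasonality
of mortality, and per-ZIP population structure beyond urbanicity. Recovery
tests demonstrate that the estimator is consistent and calibrated under
the model's own assumptions; they cannot validate those assumptions.

## Problem sizes and statistical checks

The recovery experiments run at 20k beneficiaries × 60 ZIPs × 108 months ×
25 replicates — per-ZIP occupancy ~330, nearer the real studies' ~1,300
than the 100/ZIP the default world gives, and a scale at which the full
suite completes in minutes. Coverage is tested against the pre-registered
one-sided 5% binomial bound for true coverage 0.93 (≥21/25), bias against
2 Monte-Carlo SEs; spline type-I error uses 60 replicates with the
analogous ≥51/60 bound for a true non-rejection rate of 0.90. Confidence
intervals at these sizes are wide: with ZIP-level exposure and fine strata,
within-risk-set exposure contrast comes only from staggered entry and
moves, exactly as in the real design — the original studies' precision
came from ~16 million deaths, not from richer per-person contrast. The
attenuation experiment for the two-stage method uses a traffic-dominated
temporal regime (AR sd 1.2 traffic / 0.8 secondary) and a planted RR of
1.4, because in the default regime traffic contributes too little
within-risk-set variance for attenuation to be measurable at desk scale;
the experiment's planted values are stated in the test and read from the
truth sidecar.

The independent oracle for the Cox engine is R `survival::coxph` with
`ties="breslow"` on counting-process data (eps 1e-12): β̂ and SE agree to
1e-6 relative and log-likelihoods to machine precision across 20
randomized small cohorts.

## Known limitations

* Breslow only — no Efron or exact tie corrections (incompatible with exact
  grouping at this scale); with monthly grids and very large risk sets the
  Breslow/Efron difference is small but not zero.
* Model-based (inverse-information) variances only; no robust/sandwich
  estimator, no frailty or time-varying coefficients.
* Partial-likelihood estimates from heavily stratified sparse data carry
  small-sample bias away from the null of order 1/(events per informative
  risk set); at the tested sizes it is within Monte-Carlo noise.
* The stage-1 regression is pooled; the per-ZIP variant mentioned in some
  analyses is available only as a configuration switch and is not the
  tested default.
* Single-threaded NumPy implementation; the parallelism contract is
  order-independence of sums, not actual multi-threading.
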