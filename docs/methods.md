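# Methods

## The problem

Implanted defibrillators with daily remote transmission measure seven
physiologic channels relevant to heart-failure (HF) status: 24-h mean
heart rate, nocturnal mean heart rate, heart-rate variability (HRV),
atrial high-rate episode (AHRE) burden, premature ventricular
contractions per hour (PVC/h), physical activity, and thoracic
impedance.  A composite daily *HF score* summarizes their temporal
trends; the package implements the score, the event-anchored windowing
of daily scores into 13 weekly bins, and the mixed-model comparison of
12-week pre-hospitalization trends between patients with and without a
worsening-HF hospitalization (WHFH).

## Score engine

Each day the engine looks back over an 84-day telemetry window and
computes seven component scores, each `weight × statistic` with the
statistic normalized to [0, 1]:

| component | statistic | default weight |
|---|---|---|
| 24-h HR | monotone *increase* | 20 |
| HRV | monotone *decrease* | 20 |
| nocturnal HR | trailing 28-day SD / reference SD (8 bpm), clipped | 15 |
| impedance | monotone decrease | 15 |
| activity | monotone decrease | 10 |
| AHRE burden | mean burden / 50%, clipped | 10 |
| PVC/h | monotone increase | 10 |

Monotone statistics are the positive (or negative) part of a normalized
Mann–Kendall concordance: the mean over all ordered day pairs of
`sign(x_j − x_i)`.  This choice is shift-invariant, rank-based (robust
to unit changes and outliers), exactly 0 for a constant window,
saturating at 1 for a strictly monotone one, and mean-0 under
exchangeable noise.  HRV days with AHRE burden above 20% of the day are
excluded from the HRV statistic, since atrial tachyarrhythmia corrupts
the variability measurement.  The exact functional forms of the
deployed commercial algorithm are proprietary and unpublished; these
statistics are this package's own operationalization, chosen so that
the qualitative component behaviour and the published contribution
shares are reproduced (the calibration test holds the mean 24-h HR /
HRV / impedance contributions of simulated pre-event windows within
±5 percentage points of 32 / 22 / 17%).

The composite score is the exact sum of the seven components (0–100
with default weights); a companion *index* equals score / 10.  Daily
scores are emitted only after a 30-day post-implant run-in and are
flagged invalid when the trailing-90-day transmission rate falls below
55% (the denominator is `min(90, series age)` so young series are not
penalized) or when fewer than 10 measured days remain in the window —
missingness policy is owned by the gate, not by the detectors.

**Alerts.** An episode opens on the first day of `stable_exceed_days`
(default 2) consecutive valid days with score above the nominal
threshold (default 45) and closes on the first valid day with score
below the recovery threshold (nominal − 10).  The hysteresis pair
prevents flutter around the trigger level.  Missing or invalid days
pause the consecutive-day counter and never terminate an open episode.

## Windowing

Day offsets `d = anchor − day` with `d ∈ [0, 90]` map to week
`−floor(d/7)`: 13 disjoint 7-day bins, Week 0 = offsets 0–6, Week −12 =
offsets 84–90.  Event anchors are hospital admissions at least 30 days
post implant passing the transmission gate; windows truncate at the
run-in boundary and at the day after a previous admission (repeat
admissions under 90 days apart therefore analyse only the inter-event
interval, and windows of the same patient never overlap).  Patients
without a qualifying admission anchor at their last transmitted day,
require ≥90 days of post-run-in follow-up, and are analysed as the
no-event group; the run-in requirement is applied to control anchors
for symmetry.  A weekly mean requires at least one observed day — the
55% global gate already bounds missingness and the model tolerates
unbalanced weeks.

## Mixed model

Weekly means are modelled as

```
y = β₀ + β₁·t + β₂·g + β₃·t·g + u_patient + v_anchor + ε
```

with `t = week + 12` (the intercept is then literally the Week −12
prediction), `g` the group indicator, `u ~ N(0, σ²_p)` a patient-level
random intercept, `v ~ N(0, σ²_a)` an anchor-within-patient random
intercept accounting for repeated hospitalizations, and `ε ~ N(0, σ²_e)`.
Controls contribute singleton anchor clusters, so the anchor variance
is identified by multi-anchor patients only; this keeps a single model
for both groups.

Estimation is REML by default (ML available).  β and σ²_e are profiled
out in closed form; the remaining 2-dimensional optimization over
log-parameterized variance ratios (γ = σ²/σ²_e) uses Nelder–Mead from
moment-based starting values scaled by 0.1/1/10, tie-broken by
likelihood and then by smaller component norm.  The marginal covariance
is block diagonal by patient; blocks sharing a design matrix and anchor
partition are Cholesky-factorized once and batched, which makes a
full-cohort fit (≈28 000 weekly observations) take under a second.
A deliberately naive dense multivariate-normal evaluation of the same
criterion serves as an independent oracle: tests require agreement to
1e-6 on small instances, agreement with balanced-design nested-ANOVA
closed forms, exact OLS in the zero-variance limit, and agreement with
statsmodels' `MixedLM` on a moderate nested dataset.

Group contrasts are Wald tests with normal-approximation p-values and
no degrees-of-freedom correction — appropriate for the target use at
thousands of observations, anticonservative on very small fixtures
(a documented limitation).  A perfect fit (zero residual) returns the
OLS coefficients with zero variance components; a constant response is
an error.

## Synthetic data

The simulator defines the study conditions under which everything is
tested.  Defaults: 259 event patients with 369 hospitalizations in
total (1–3 per patient) and 1791 controls; follow-up uniform on
300–1000 days; daily transmission probability 0.9; admissions at least
121 days post implant (room for run-in plus a full window) and at least
45 days apart, so sub-90-day gaps occur and exercise truncation;
group-specific covariate prevalences matching the pooled cohort's
baseline table.  One integer seed is split deterministically per
patient, making any patient subset reproducible independently of
cohort size.

**Component-score route.**  Expected component values interpolate
linearly between the group's Week −12 and Week 0 weekly means
(trajectory endpoints default to the pooled-cohort values: event-group
composite 42.3 → 51.6, control 30.8 → 29.6 as the sums of the component
entries), anchored at week midpoints so weekly bin means are exactly
linear in the week index; days outside any 91-day window hold the
Week −12 baseline, and each day is attributed to the next upcoming
admission.  A per-component `shape` override supports a plateau form
(flat until a final 4-week rise) for channels that saturate early.  On
top of the mean structure sit per-component patient intercepts, anchor
intercepts and daily residual noise whose variances split the squared
cross-sectional weekly SD in shares 0.5 / 0.2 / 0.3.  Values are
floored at zero with a *mean-preserving location adjustment*: the
pre-floor Gaussian location is solved (Newton, convex problem) so that
the floored expectation equals the requested mean.  Configured
trajectory means are therefore recovered exactly in expectation at any
noise level — the alternative (naive flooring) would inflate small
means such as the PVC component by several points.  The price is that
*realized* dispersions are smaller than the nominal SDs for components
with substantial mass at zero, and the realized composite weekly SD
(≈10 points) is below the nominal cross-sectional value; mean
trajectories and contrasts, which are what the analysis estimates, are
unaffected.

**Telemetry route.**  Raw channels in physiologic units with Gaussian
daily noise around group baselines; event patients drift linearly over
the 182 days before each admission (rising 24-h HR and PVC rate,
falling HRV, impedance and activity, rising nocturnal-HR dispersion and
AHRE level; AHRE burden is an exponentially distributed multiple of a
slowly rising level).  Drift rates are calibrated analytically against
the expected Mann–Kendall statistic so that mean pre-event component
values approximate the event-group Week −12 trajectory means under the
default engine weights.  Controls are stationary, so their trend
components are near zero by construction — the telemetry route
reproduces the event group's component structure and the engine's
mechanics, not the control group's elevated baseline levels; analyses
that need both groups' levels use the component-score route.  No
circadian, seasonal or medication structure is modelled, and
within-patient day-to-day autocorrelation beyond the random intercepts
is not simulated.

## Numerical and design choices

* Transmission-rate denominator `min(90, series age)`; rate evaluated
  at the admission day itself for event anchors.
* Repeat-event windows start the day *after* the previous admission,
  which both matches the inter-event analysis interval and guarantees
  non-overlap.
* Weekly means are unweighted by the number of observed days.
* Chi-square tests are uncorrected and the Mann–Whitney U uses the
  tie-corrected normal approximation without continuity correction.
* Component weights, thresholds, the AHRE saturation point (50%), the
  HRV exclusion cutoff (20%) and the nocturnal-HR reference SD (8 bpm)
  are configuration, not constants.
* The composite is not capped: with default weights its ceiling is the
  weight sum (100).

## Problem sizes used by the test suite

Unit and property tests run on cohorts of tens of patients.  The
full-cohort recovery check simulates 2050 patients / 369
hospitalizations (≈28 000 weekly observations) three times; the
acceptance script averages five such replicates.  Null calibration of
the slope-contrast test uses 200 replicates of a 50-patient cohort and
checks the rejection rate against the binomial 95% band around 0.05.
Monte-Carlo convergence tests use 3-standard-error tolerances.

## Known limitations

* The component functional forms approximate an unpublished proprietary
  algorithm; absolute component values are comparable only within this
  package.
* Wald normal p-values are anticonservative for small samples; no
  Satterthwaite/Kenward–Roger correction is provided, and random slopes
  and non-Gaussian responses are out of scope.
* The simulator's weekly SDs are nominal pre-floor values (see above);
  zero-inflation of low-mean components makes their weekly
  distributions non-Gaussian, which the mixed model absorbs at the cost
  of efficiency, not bias.
* The static baseline risk offset some deployed algorithms add at
  implant is intentionally not modelled.
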