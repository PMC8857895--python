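# Methods

## Setting and data model

The package targets ecological-momentary-assessment cohorts of daily-regimen
PrEP users observed with two instruments: a MEMS cap recording the timestamp
of every pill-bottle opening, and a brief weekly online survey recording,
for each of the preceding seven days, whether condomless anal sex (CAS)
occurred, how many episodes (0/1/2/3-or-more) and with how many partners
(0/1/2-or-more).  Analysis time is centred on a calendar changepoint —
2020-03-16, the start of UK COVID-19 control measures — so that `t` counts
days since the changepoint and `pandemic = I(t >= 0)` splits follow-up into
pre and intra periods.

The daily panel has one row per participant per calendar day between
enrolment and end of follow-up.  `dose_day` is 1 when the cap opened at
least once that local calendar day (multiple openings collapse to one
dose-day; the count is kept for diagnostics).  The day boundary is midnight
by default; a configurable `day_cut_hour` reassigns small-hours openings to
the previous evening.  Survey-covered days populate the CAS fields; days
without a survey are left missing and are never imputed as zero — all
descriptive denominators are *observed* days, with separate observability
flags for dosing and CAS because the two instruments can fail independently.

## Episode coverage

A CAS episode on day `d` is **covered** when `dose_day = 1` on every day of
`{d-3, ..., d-1}` and `{d+1, d+2}`.  The window lengths and an optional
requirement of a dose on `d` itself are parameters of `CoverageRule`; the
default reading takes "3 days prior / 2 days following" as the consecutive
calendar days immediately adjacent to the episode.  If any required day
falls outside the participant's observed panel the episode is
**unassessable** and excluded from denominators (assessed-subset semantics).
Episodes — not CAS days — are the unit: a day reporting `k` episodes
contributes `k`, all inheriting the day's status, since within a day the
dosing context is identical.  Counts capped at "3 or more" ("2 or more" for
partners) are stored as 3 (2), so episode-weighted totals and daily means
are lower bounds.

Participants on an event-based (on-demand) regimen are excluded from
coverage analyses upstream; their dosing is aligned to risk by design and
the daily-coverage rule does not apply.

The sensitivity filter for inconsistent MEMS use works on follow-up
intervals (enrolment to follow-up 1, follow-up 1 to 2, ...): an interval is
flagged when |percent implied by the self-reported use level − MEMS percent
of dose-days| exceeds a threshold (default 40 percentage points; levels map
daily→100, most days→75, about half→50, occasionally→25, rarely/never→5).
The underlying study describes such a screen without publishing its exact
criterion, so this transparent, configurable rule is this package's own
re-specification; on contaminated synthetic data it moves measured coverage
toward latent-truth coverage, which is the property the tests check.

## Trend models

Daily outcomes are modelled with two-level mixed-effects regressions on the
changepoint-centred axis:

* fixed part: restricted cubic spline in `t` (Harrell parameterisation,
  `k` knots → `k−1` terms, linear tails), the pandemic indicator, optional
  spline×pandemic interactions, optional lagged-dose term;
* random part: participant intercept and pandemic indicator with
  unstructured 2×2 covariance (Cholesky-parameterised, so estimates are
  always PSD; near-zero variances are flagged as boundary estimates).

Default knots are (−126, −24, 64, 184) for the 4-knot dosing model and
(−122, −39, 23, 91, 188) for 5-knot sexual-behaviour models — the locations
used in the motivating cohort — with Harrell quantile placement available
for other data ranges.  "Pandemic time" enters both fixed and random parts
as the indicator `I(t ≥ 0)`; a continuous alternative (`max(t, 0)/100`) is
exposed behind a flag.  Binary outcomes use the Bernoulli-logit likelihood;
capped ordinal counts use a cumulative-logit (proportional-odds) likelihood
with the identical random-effect structure, the cap category modelled as its
own top category.

### Estimation

The marginal likelihood integrates the bivariate random effect per
participant by adaptive Gauss–Hermite quadrature: the integrand's mode and
curvature are found by damped Newton (vectorised across participants), the
tensor-product Hermite grid is recentred and rescaled there, and one node
per dimension recovers the Laplace approximation.  The default is 7 nodes
per dimension; the simulation studies in the test suite use 5 (confidence
interval calibration) and 3 (test-size calibration) nodes, which on this
class of data agree with high-node likelihoods far beyond the Monte-Carlo
noise of those studies.  Scores are posterior expectations of the
complete-data score evaluated on the same grid — the quadrature
approximation of the exact marginal score — giving BFGS an analytic
gradient; damped Newton steps with a finite-difference Hessian polish the
optimum (and rescue line-search precision-loss exits), and non-convergence
raises a diagnostic error with the gradient norm.  Design columns are
standardised internally for conditioning and estimates mapped back.

Standard errors are cluster-robust over participants by default: meat = sum
of outer products of per-participant scores with the small-sample factor
G/(G−1); bread = inverse observed information (finite-difference Jacobian of
the analytic score).  The joint test of the spline×pandemic block is a Wald
chi-square on that block with the robust covariance, df = block size, with
the chi-square reference distribution.  Marginal probability curves
integrate the inverse-logit over the estimated random-effect distribution
with a 40-node Gauss–Hermite grid (matches Monte-Carlo averaging over 1e5
draws to ~5e-4); extrapolation beyond the fitted time range triggers a
warning.

The lagged association model pairs the dose on day `t − lag` (default lag
1 day; the adjacent-day coupling is this package's declared interpretation)
with the CAS outcome on day `t`, dropping each participant's first `lag`
days, with the pandemic indicator and optionally its interaction with the
lagged dose.

## Coverage relative risk

The log-binomial model (binomial likelihood, log link) is fitted to
episode-level rows with the period indicator; exp(slope) is the relative
risk of coverage intra- vs pre-changepoint.  Fisher scoring uses
step-halving and rejects any step that would push a fitted probability to 1
(boundary hits are flagged).  With the single saturated binary covariate the
point estimate equals the ratio of observed coverage proportions exactly,
which is what makes the published contrasts reproducible from aggregate
counts alone.  The sandwich covariance clusters scores on participant and
applies G/(G−1) (configurable and reported); intervals are Wald on the
log-RR scale.  Episode-level rather than participant-aggregated rows are
used for transparency — with participant clustering the two are
score-equivalent.

## Synthetic cohorts

`simulate_cohort` draws the latent layer from exactly the structure the
trend models assume: enrolment dates uniform over 2019-09-24..2020-01-27,
270 days of follow-up, geometric withdrawal with daily hazard 3.9e-4 (~10%
attrition over 270 days, matching the scale of attrition reported for the
motivating cohort), spline + pandemic-step linear predictors for daily
dosing and CAS, a one-day lagged dosing term in the CAS predictor, and
bivariate normal random effects (dosing covariance 4.47/3.75 with −1.55;
CAS covariance 1.02/1.03 with 0.06 — the values estimated in the motivating
cohort, used here as generator truth).  Intercepts are on the
conditional (median-participant) logit scale: logit 0.85 ≈ 0.70 daily dosing
and logit −2.38 ≈ 0.085 daily CAS at the changepoint, inside the reported
pre-pandemic ranges.  Episode and partner counts on CAS days are drawn from
conditional categorical distributions whose defaults imply ~1.87 episodes
and ~1.54 partners per CAS day, reproducing the reported per-day means of
0.17 and 0.14 at a ~9% daily CAS rate.  PrEP and CAS random effects are
drawn independently (no cross-process correlation is published).

The observation layer emits one cap event per latent dose-day at a random
daytime hour, thinned by pocket-dose draws (dose taken, cap untouched) and
by whole non-monitored periods, and augmented by curiosity openings on
non-dose days; weekly surveys report the latent CAS fields faithfully with
full response (the motivating study reports high follow-up but no rate, so
none is defaulted).  Clinic follow-up self-reports at ~90/180/270 days
categorise the *latent* dose fraction, so self-report-vs-MEMS discrepancies
are pure observation noise — exactly what the sensitivity filter screens.

What the generator does not emulate: survey non-response and recall error,
partner-type structure, event-based regimens, STI acquisition, seasonal or
weekday patterns, and autocorrelated within-person residuals beyond the
random effects.  Passing recovery tests therefore demonstrate correctness of
the estimators under the assumed model, not robustness to those violations.

## Calibration studies (test suite)

* Confidence-interval coverage: 200 cohorts of 60 participants × 270 days at
  generator truth (pandemic OR 0.44, dosing covariance block above); the
  robust 95% Wald CI for the pandemic effect must cover the truth in
  90–99% of replicates.
* Test size: 500 null cohorts (no interaction terms in the generator) of 60
  participants × 120 days, 4 quantile knots; the robust Wald joint test of
  the spline×pandemic block must reject at the 5% level between 2.5% and
  7.5% of the time.  Cohort size here is the package's choice for a
  single-CPU study; the statistic's calibration is what is under test.
* Determinism: identical config + seed reruns of the pipeline must produce
  byte-identical output digests (the run manifest records them).

## Known limitations

* The proportional-odds model assumes a common spline/pandemic effect across
  category thresholds; no test of that assumption is provided.
* Cluster-robust Wald inference relies on ~60 clusters; with far fewer
  participants the G/(G−1) correction is insufficient and intervals
  anti-conservative.
* The log-binomial boundary guard flags, but does not re-parameterise,
  fits pressed against probability 1; a Poisson-with-robust-SE fallback is
  deliberately out of scope.
* Means of capped ordinals are lower bounds; no attempt is made to recover
  uncapped counts.
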