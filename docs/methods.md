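# Methods

This note documents the modelling choices, simulator assumptions, defaults
and numerical decisions behind `surrocohort`, and what the validation suite
does and does not establish.

## Setting and data model

The package targets longitudinal claims extracts: a patients table
(demographics, one enrollment span, coverage and plan descriptors), diagnosis
claims (patient, date, condition code) and pharmacy claims (patient, drug
class, dispense date, days supplied).  Condition and drug taxonomies are
opaque codes; mapping real coding systems (ICD, NDC) onto them is external
configuration.  Internally all dates are integer day offsets from a fixed
epoch and every interval is half-open `[start, end)` in day units; calendar
dates exist only at the I/O boundary (ISO-8601 CSV).  Multiple enrollment
spells are out of scope: each patient has a single span, and users with
spell-level data should pre-merge or split patients upstream.

Cleaning removes pharmacy records with non-positive or implausibly long
supplies (default cap 365 days) and records dispensed outside enrollment.
These are logged, not raised: real extracts contain them routinely.

The RA index date is the first RA diagnosis claim.  "Six months" for the
incident-case flag is fixed at 183 days with a strict inequality; the flag
marks patients whose index plausibly represents disease onset rather than a
prevalent case carried into the database.

## Treatment episodes

Dispensings merge into continuous-therapy episodes under two rules:

* **stockpiling** — overlapping supply queues: a refill dispensed before the
  current supply runs out extends coverage end-to-end
  (`end = max(end, date) + supply`).  This is the common pharmacoepidemiology
  convention and is what makes days-on-therapy well defined under early
  refills; whether to truncate instead is configurable only by pre-editing
  the dispensing table, a deliberate simplification.
* **inclusive grace** — a gap of exactly `grace_days` (45 for OS cessation)
  still continues the episode, reading "within N days" inclusively.

Episodes truncated by enrollment end carry `ceased=False` so cessation
analyses censor there instead of counting an artifactual event.  A cessation
within `grace_days` of enrollment end is still treated as observed; strictly,
the absence of a refill inside the grace window is then unverifiable, a known
(small) limitation.

The validation oracle for episode construction is an independent brute-force
route: a day-by-day pill-count walk with a supply queue, followed by merging
covered runs whose gaps are at most the grace period.  The two
implementations agree exactly on randomised histories.

## Unmatched time-to-event design

Sub-cohort membership is decided by OS episode coverage of any day in the
inclusive window [index−30, index+30]; the window absorbs recording
inaccuracy in prescription and diagnosis dates.  Design choices the source
design leaves open, resolved here:

* sub-cohort I events are any OS dispensing after the index (not only those
  opening a new episode); by the window definition the first such dispensing
  necessarily falls after index+30.  The clock nonetheless starts at the
  index and no immortal-time correction is applied — this mirrors the design
  as specified and is a documented caveat, quantified by the
  ensemble-truth calibration in the validation suite rather than assumed
  away;
* sub-cohort II patients whose qualifying episode ended on or before the
  index (possible through the window lookback) have non-positive follow-up
  and are excluded with a log entry;
* baseline covariates (co-morbidities from diagnosis claims, co-medications
  from pharmacy claims, prior OS) are ascertained from all records on or
  before the index day, not a fixed lookback;
* age strata are 20–50, 51–70, 71–88 with age 70 in the middle band (the
  printed bands overlap at 70); ages outside the range join the nearest band;
* calendar year of the index enters the full model as indicator terms against
  the earliest year.

Fitting uses lifelines' time-varying Cox implementation (Efron ties),
stratified baselines, and Wald inference.  Covariate selection retains
adjusters with p < 0.1 (strict) from the full model; the exposure is always
forced.  Two numerical fallbacks: if the full design is singular the
calendar-year terms are dropped first; and a monotone partial likelihood
(a binary adjuster whose carriers all reach events before any is censored —
`prior_os` does this in flare-heavy cohorts) triggers a light ridge refit
(penalizer 1e-3, labelled `cox_tv_ridge`).  Non-convergence is always
surfaced as a flagged result, never silently.

## Matched new-user design

New users are patients whose first-ever statin dispensing follows at least
365 days of membership, with an RA claim before that date and age > 20 at the
first RA claim (excluding juvenile arthritis).  Matching is 1:1 without
replacement on sex and exact integer age at the exposed patient's index date
— integer completed years, the finest granularity birth-year data support.
Exposed patients are processed in randomised order and candidates drawn
uniformly under the run seed, so no early exposed patient is systematically
advantaged; a patient consumed as a match is not later re-enrolled as
exposed.  Candidates need no statin dispensing in the prior 365 days (a
past user who stopped more than a year before qualifies), the same
membership, RA and age conditions, and must be enrolled at the index.

Outcomes are evaluated on `[index+90, index+455)`: the 90-day run-in is the
time after which an initiator can be considered fully exposed, and events
during it are not outcomes — OS use in the run-in enters as a baseline
covariate instead.  Unexposed follow-up is additionally censored at the
patient's own first statin dispensing (crossover); the binary outcome for
censored patients is evaluated on the truncated window.  Enrollment ending
during the run-in leaves zero follow-up; such records are retained in the
tables and dropped by the count models (no information under an offset of
log follow-up).

Analyses: conditional logistic regression within pairs (the no-covariate
case uses the exact closed form OR = n10/n01 with Wald SE √(1/n10+1/n01);
with covariates the conditional likelihood is maximised numerically); a
paired Wilcoxon signed-rank test on within-pair differences in the
proportion of follow-up days on OS (zeros dropped, mid-ranks for ties, Pratt
handling available); an unadjusted negative binomial; and a zero-inflated
negative binomial with the offset on the count part.  Covariate screening
for the ZINB follows the two-part procedure — a multivariable logistic model
for the binary part and a multivariable NB for the count part, each at
p < 0.1 — with the union of survivors entering both parts, since the fitted
mixture shares one design matrix.

ZINB estimation uses warm starts (a zero/non-zero logistic fit plus an NB
fit on the non-zero rows) followed by BFGS, with a Nelder–Mead/BFGS restart
on non-convergence; cold-started fits of this likelihood routinely diverge.
The model-implied marginal zero fraction, `mean(pi + (1-pi)·NB(0))`, is the
diagnostic compared against the empirical zero fraction.

The propensity diagnostic fits a logistic model of exposure on all baseline
covariates, their first-order pairwise interactions and age squared;
continuous covariates are centred before interactions to reduce
collinearity, constant and duplicate columns are dropped, and perfect
separation is flagged rather than raised.  Overlap is summarised by shared
20-bin score histograms and an overlap coefficient (the summed per-bin
minimum of the two groups' shares).

## Digit-preference profiling

Recorded durations heap at prescribing-convention values (multiples of 7, 10
and 30 days).  The profile counts mass at those multiples and computes an
excess statistic: the share of observations at preferred values above a
smooth local baseline (the mean count of ±2-day neighbours that are not
themselves preferred values).  Because no standard test exists for this
observation, significance comes from a jitter-resampling null: each duration
is displaced uniformly within ±2 days (destroying heaping, preserving the
coarse shape) 2,000 times by default, and the p-value is the upper tail of
the null excess.  Under smooth duration distributions the false-flag rate is
at or below nominal; half-strength heaping is detected essentially always at
a few hundred durations.

## Synthetic-claims generator

The generator encodes the qualitative structure of the target data source,
with known ground truth:

* **flares** — an inhomogeneous Poisson process per patient with intensity
  `flare_rate_base/365 × frailty × exp(confounder effects) ×
  exp(statin_flare_logHR × exposed(t))`, piecewise constant around the statin
  initiation day.  Frailty is log-normal with mean 1 and variance
  `frailty_var`; it creates the between-patient heterogeneity that makes the
  marginal hazard ratio attenuate over follow-up, which is why effect
  recovery is judged against an ensemble truth rather than the conditional
  parameter;
* **statin initiation** — exponential waiting time with hazard
  `statin_init_rate × exp(confounder effects)`; the same covariates act on
  flares, so initiation is confounded by construction; refills persist to
  enrollment end;
* **oral steroids** — each flare triggers a dispensing with probability
  `os_response_prob` unless the patient is contraindicated
  (`p_contraindicated`, the structural-zero class); treated flares draw an
  exponential treated duration (mean 1.5× the per-dispensing mean) and emit
  refills at supply exhaustion, giving the 45-day cessation rule something
  to merge;
* **digit preference** — with probability `digit_pref_prob` a drawn supply
  snaps to the nearest positive multiple of 7 or 30, ties to 30 (the 30-day
  peak dominates in practice).

Defaults describe a plausible RA claims cohort: 11 calendar years, mean
4-year membership, 75% female, ages 20–88, 1.5 flares/patient-year, frailty
variance 0.5, statin initiation 0.10/patient-year, confounding by age and
cardiovascular disease (log HR 0.4 and 0.5 on both pathways), 75%
contraindicated, 60% flare-to-prescription response, 21-day mean OS supply,
60% digit preference.  Together these yield roughly 80% of patients with no
OS use — the mixture of structural zeros and untreated low-frailty patients
that motivates the zero-inflated outcome model.  OS dosage is not simulated,
only days supplied, matching the analyses actually run.

What the generator does **not** emulate: dependence of flare risk on disease
duration or treatment history, statin discontinuation and re-initiation,
enrollment gaps, coding error or claim reversals, and dose information.
Passing validation therefore shows the designs and fits are correct under a
faithful generative null/effect structure — not that any real-world estimate
is unbiased, which depends on assumptions (no unmeasured confounding,
surrogate validity) no simulation can certify.

## Validation experiments and problem sizes

The experiments behind `scripts/acceptance.py` and the end-to-end test
suite, with the sizes the package runs them at:

* episode oracle: 1,000 random histories (≤10 dispensings, supplies ≤90
  days) × grace ∈ {0, 30, 45}, exact agreement required;
* person-time: 1,000 simulated patients; counting-process rows must
  partition follow-up exactly and row exposure must match day-level
  membership in oracle-built coverage;
* type-I error: 500 null replicates of 1,000 patients; Wald rejection at 5%
  must stay inside [0.025, 0.075] (the 99% Monte-Carlo band) for the
  initiation-design Cox fit and for the ZINB count part (80% structural
  zeros, rate ratio 1);
* effect recovery: 300 replicates at true flare log HR = log 0.7, judged
  against the mean estimate of 25 replicates at 10× size (the ensemble
  truth): mean within ±0.05, CI coverage of that truth in [0.92, 0.98];
* ZINB recovery: 100 samples of 6,000 with 80% structural zeros and count
  rate ratio 0.88 — a regime mirroring the observed ~80% zero OS use —
  mean recovered rate ratio within ±0.03, model-implied marginal zero
  fraction within 2 points of empirical;
* conditional logistic: 200 random 1:1 tables, closed form vs n10/n01 to
  machine precision (cross-checked against the numerical conditional MLE in
  unit tests);
* digit preference: flag rate > 90% at `digit_pref_prob = 0.5`, ≤ 10% at 0;
* matching: every emitted pair re-verified by an independent predicate sweep
  over the raw claims tables.

One master seed spawns independent substreams for simulation, matching order
and resampling, so every reported number is a deterministic function of
(configuration, seed).

## Known limitations

* Immortal-time structure of sub-cohort I is reproduced, not corrected.
* Recurrent OS episodes per patient (repeated initiation/cessation) are not
  modelled; only the first qualifying episode counts.
* 1:M matching and caliper relaxation are out of scope.
* The ZINB shares one covariate design between its two parts after the
  two-part screen.
* The coverage band for the effect-recovery check is a property of this
  generator's attenuation structure; different frailty variances would move
  the ensemble truth.
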