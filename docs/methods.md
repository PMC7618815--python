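# Methods

This note documents the models, conventions and numerical choices behind
`moodcue`: what the pipeline computes, what the synthetic-cohort generator
does and does not emulate, and where open design questions were settled.

## The protocol and its schedule

The default `StudyDesign` describes a 10-week protocol with 5 testing
sessions per week (sessions on weekdays 1–5 of each 7-day block; calendar
day of session *s* is `7·(w−1)+d`).  Each session presents 40 visual-search
trials, ten per cueing condition:

| condition   | repetition structure                                   | learning axis |
|-------------|--------------------------------------------------------|---------------|
| novel       | 10 new configurations per session, never repeated      | week (generic practice) |
| alternate   | one 10-configuration set on odd sessions, another on even sessions | week |
| daily       | 10 configurations repeated once per session, every session | week |
| within_day  | 1 configuration repeated 10× within a session, unique to that session | within-session repetition 1–10 |

Displays place one rotated-T target among 11 rotated-L distractors on an
invisible 8 × 6 grid with four right-angle orientations.  The grid geometry
is a package convention (standard contextual-cueing practice), parameterized
in `StudyDesign`; the analysis consumes only trial metadata, so the exact
eccentricities are irrelevant downstream.  Within a configuration the target
cell and every distractor (cell, orientation) pair are identical at all
repetitions; novel configurations are globally unique across the entire
study (enforced by exhaustive identity checks at generation time).

Trial order is randomised by rejection sampling (retry cap 10 000) under the
single constraint that two within-day trials never appear consecutively;
rejection sampling keeps the distribution uniform over admissible orders.
"Odd/even days" for the alternate condition means parity of the 1-based
scheduled session index, not the calendar date, so missed sessions cannot
flip a configuration between parity sets.  Repetition indices are 1-based
(power-law fits need a positive abscissa): occurrence order within the
session for novel and within-day trials, study week for daily and alternate
trials.  Presentation timings (500 ms prestimulus, 1000 ms ITI) are carried
as metadata only.

## Mood model and calibration

Daily mood is a 10-item PANAS short form: five positive and five negative
items, each rated 1–5, summed to positive/negative affect scores in 5–25.
Instability is the time-adjusted root mean square of successive differences
with **divisor N** (the number of ratings) — not the conventional N−1 —
matching the definition used in the field literature this pipeline targets;
`trmssd(..., divisor="n-1")` exposes the conventional variant.  Timestamps
are calendar days at daily resolution, the resolution of the synthetic
data; the time adjustment (dividing each difference by its gap in days)
keeps missing days from inflating the statistic, which the test suite
verifies on smooth series with deleted interior points.

The generator draws a latent affect sum per calendar day from a
mean-reverting AR(1): persistence φ = 1 − `mean_reversion` (default 0.5),
innovation variance set so the stationary lag-1 successive-difference SD
equals the `delta` parameter.  The AR(1) form is an artifact convention —
nothing in the target literature commits to a generative law for daily
affect — chosen as the simplest stationary process with independently
tunable mean and successive-difference scale.  Observed sums are the latent
values clipped to [5, 25] and rounded; items are equal shares with
largest-remainder rounding plus two random unit transfers (sum-preserving,
clipped to 1–5).

Clipping, rounding, day gaps (weekends, skipped sessions) and the divisor-N
convention all shift the realized moments away from the latent parameters,
so `calibrate_mood_params` moment-matches by simulation: it repeatedly
simulates a 400-participant cohort under the attended-day pattern, compares
the realized cohort-mean affect mean and tRMSSD to their targets, and
updates the latent mean additively and the latent difference scale
multiplicatively until both are within 2% (usually < 10 iterations).  Common
random numbers (a fixed internal seed) make the iteration deterministic;
recovery is then verified on independent seeds.  Default targets: high-MDQ
group mean/tRMSSD of negative affect 7.75 / 2.81 and positive affect
11.74 / 3.97; low-MDQ 5.90 / 1.61 and 11.51 / 3.35.

## Reaction-time model

Clean RT level is a power law on the same axes the analysis fits — a
deliberate choice so slope recovery is unbiased by construction (simulating
per-repetition curves and averaging would conflate the axes):

* daily: `a · w^b_daily`, alternate: `a · w^b_alt` (w = study week 1–10),
* novel: `a · w^b_prac · n^b_novel_within` (n = within-session position),
* within-day: `a · w^b_prac · k^b_within` (k = repetition 1–10).

Multiplicative lognormal noise is normalized to mean one (log-scale shift
−σ²/2, default σ = 0.25), so intercepts are interpretable as mean RT in ms.
All intercepts default to 1362 ms, the week-1 novel baseline; the generic
practice exponent defaults to `b_prac = −0.027`, which carries that baseline
to ≈ 1290 ms by week 8.  Group/condition exponent gaps are additive with no
group × condition interaction: relative to `b_prac`, daily −.0195 (low) /
−.0105 (high) and alternate −.0105 (low) / −.0015 (high), making the
condition means (daily −.015, alternate −.006) and group means (low −.015,
high −.006) hold simultaneously.  Within-day exponents are −.054 (low) and
−.043 (high) with the novel within-session exponent 0.

Contamination is drawn per trial from mutually exclusive categories so the
cleaning cascade can be audited stage by stage: out-of-bounds RTs
(`oob_rate`, default 0.0012; replaced by a negative or > 8000 ms value),
extreme-but-plausible outliers (`outlier_rate`, default 0.017; uniform
4500–7900 ms), and unrecorded trials (`unrecorded_rate`, default 0.0024;
correctness lost).  Error trials (`error_rate`, default 0.05) are drawn only
among otherwise-clean trials.  Sessions are skipped independently at
1 − `compliance` (defaults 0.92 high / 0.94 low), and one attendance draw
per day governs both the mood rating and the task session.  Planted counts
are recorded in the dataset manifest; with RT noise switched off, each
cleaning stage removes exactly its planted process (tested).

What the generator does **not** emulate: mood–cognition coupling (none is
built in, so group differences in learning slopes arise only from the
configured exponents), circadian or within-day mood dynamics, autocorrelated
attendance (real participants miss runs of days), RT autocorrelation within
sessions, and fatigue or time-of-day effects.  Passing recovery tests
therefore show that the *pipeline* measures what the generator encodes, not
that real data satisfy these assumptions.

## Cleaning conventions

Stages run in order: bounds (`[0, 8000]` ms closed interval), unrecorded,
error removal (RT branch only — accuracy analyses keep error trials), then
the 3 SD trim.  The trim computes mean and sample SD (ddof = 1) **once** per
participant × condition cell (the four cueing conditions, not condition ×
week) and removes RTs above mean + 3 SD.  One-sided upper trimming follows
the literal "> 3 SDs from the mean" rule combined with RT practice (long
upper tails); `two_sided=True` is available.  Cells with fewer than two
trials are left untrimmed with a warning.  Participants with paired
mood+task data in fewer than 3 distinct study weeks are excluded before
cleaning.

## Learning-slope estimation

"Slope" throughout means the power-law **exponent** b, not the tangent of
the fitted curve: the magnitudes involved (−.006 to −.054) are
dimensionless and the normalization arithmetic operates on one slope value
per condition.  Weekly epochs are calendar-day blocks; across-day fits
require ≥ 4 epochs per condition (3 points exactly determine a 2-parameter
curve plus noise; threshold configurable).  Within-day fits pool
repetition-indexed mean RTs across all sessions into one 10-point curve per
participant and condition rather than fitting each session's 10 trials
separately, which would be noise-dominated.

Fits minimise MSE on the raw RT scale (lognormal trial noise averages to
unbiased epoch means there), initialized from the log-transform OLS solution
and refined by Levenberg-Marquardt with a 1e−12 relative cost tolerance;
non-convergent fits are flagged and excluded from group tests.  Exponential
and linear families are fitted on identical points for MSE comparison; ties
prefer the power family.  Family discrimination between power and
exponential is weak at single-participant noise (the curves nearly coincide
for shallow exponents over 10 points) and sharp on condition-mean curves,
where the comparison is meant to be run.

Normalized slopes subtract the novel-condition exponent from the repeated
condition's exponent on the same axis (`repeated − novel`), so negative
values mean faster learning in repeated contexts, i.e. a cueing benefit; the
opposite subtraction order is available via the `order` flag.  This
convention makes the subtraction direction consistent with reporting
negative means for benefits.  Normalized slopes are invariant to rescaling
all RTs and to any shared multiplicative practice factor (both tested).

Novel-RT instability is the day-unit tRMSSD of each participant's daily mean
novel-condition RT; cohort-level extreme values (> Q3 + 3·IQR) are flagged
and excluded from group tests.

## Statistics

The mixed ANOVA uses the classical sums-of-squares decomposition for one
between × one within factor, with partial η² = SS_effect / (SS_effect +
SS_error).  Greenhouse–Geisser ε comes from the eigenvalues of the
doubly-centred covariance of the repeated measures **pooled within groups**
(the SPSS/afex convention; pingouin's grand-covariance ε differs slightly
and the cross-check tests allow for that), clipped to [1/(k−1), 1].  The
correction is applied when Mauchly's test rejects sphericity at .05 (or is
undefined on a degenerate covariance); `correction="always"/"never"` are
available, and k = 2 is spherical by construction (ε = 1).  Zero
error-sums-of-squares inputs report F = 0 with a `degenerate` flag instead
of failing, so synthetic edge cases cannot crash the pipeline.  t-tests are
Student pooled-variance by default (df = n₁+n₂−2), Welch via flag; Cohen's
d uses the pooled SD.  Correlations run Shapiro–Wilk on each variable and
use Pearson only when both pass at .05, Spearman otherwise.  No
multiple-testing adjustment is applied; post-hoc pairwise machinery beyond
this is out of scope.

The novel-RT week ANOVA uses complete cases (participants present in all
ten weeks), which is why its subject count can drop below the cohort size.

## Problem sizes and verification

The acceptance script and the recovery tests use the study-scale
configuration: 37 participants per group, 50 scheduled sessions, 10
replicate cohorts, chosen as the cohort size the pipeline is designed
around.  The type-I-error check runs the mood-branch group test on 200 null
cohorts of 20 participants per group.  Unit-level oracles include
hand-computed tRMSSD and sums-of-squares values, an exhaustive profiled
grid search for the power fits, pingouin as an independent ANOVA
cross-check, and closed-form expectations (lognormal mean identity, the
√((N−1)/N)·δ tRMSSD expectation for equally spaced latent series).

## Known limitations

* The mixed ANOVA requires balanced within-subject data; unbalanced designs
  are rejected rather than fitted (no mixed-effects fallback).
* Hierarchical/mixed-effects learning-curve models and trial-level learning
  models are out of scope; fits are per participant.
* The inclusion rule and all timestamps assume daily resolution; clock-time
  tRMSSD would need sub-day timestamps.
* Calibration matches first and second successive-difference moments only;
  higher moments of real affect series (zero-inflation, skew) are not
  reproduced.
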