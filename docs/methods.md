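# Methods

`stoptrial` implements an observational emulation of a treatment-
discontinuation ("stop") trial from longitudinal memory-clinic registry
data, as used to study what happens to cognition and survival when
patients with Alzheimer's disease stop cholinesterase-inhibitor (ChEI)
treatment after a reimbursement-policy change.  This note documents the
models, the assumptions they encode, the synthetic-data generator, and the
design decisions that were genuinely open.

## Design: sequential target trials

The causal contrast is the observational analogue of an intention-to-treat
effect: being assigned to discontinue versus continue at baseline, with
later switches ignored.  A separate trial is emulated at every calendar
month of a 12-month enrolment window; a patient enrols in a trial at every
consultation month at which all criteria hold:

- age over 18;
- an Alzheimer's-disease diagnosis recorded at or before the visit;
- an MMSE at the visit inside the eligibility band (default 10-30
  inclusive; the lower bound is configurable because registry protocols
  state it both as ">= 10" and "> 10" — we adopt the inclusive reading);
- ChEI treatment recorded within the previous six months (the baseline
  visit itself counts, the package's resolution of an ambiguity in the
  protocol wording);
- a follow-up visit no more than 12 months later (otherwise the
  discontinuation date is too uncertain to use).

Treatment status is interval-censored: a patient is seen on treatment at
one visit and off at a later one.  Discontinuation is conservatively dated
at the last visit with recorded treatment before the first record of
non-use, which tends to understate the treatment effect; from that month
the patient is in the discontinuation arm for every later enrolment.  This
convention necessarily uses the later visit that *reveals* non-use, so
"no look-ahead" holds in the attainable sense that removing any visits
after the first non-use record leaves assignments unchanged.

Baselines are restricted to months with an MMSE-bearing visit: enrolment
happens at consultations, and the MMSE band cannot be checked without a
score.  A patient therefore contributes at most one block per in-window
visit rather than mechanically twelve.

The blocks are stacked into one dataset with trial month as a baseline
covariate.  Repeated inclusion of patients is handled exclusively by the
patient-level cluster bootstrap (all of a patient's blocks are resampled
together) — not by the model covariance — mirroring the source design.

## Weighting

Confounding by indication is addressed with stabilized inverse probability
of treatment weights.  A single pooled main-effects logistic model is fit
across the twelve trials for Pr(discontinue | covariates, trial month);
each block's weight is the marginal probability of its own arm divided by
its fitted propensity.  Trial month enters as linear + quadratic terms by
default rather than dummies: stopping concentrates early in a policy-driven
window, so late months can contain a single arm and month dummies then
separate.  Binary covariates whose arm-by-level cell is empty merely
because the flag is sparse (expected minority-arm carriers below ten) are
dropped with a log note; an empty cell on a well-populated covariate
raises, naming the covariate.  Adequacy is judged by absolute standardized
mean differences (SMD) below 0.1 on every covariate, with weighted means
and frequency-weighted variances, and the proportion-based variance for
binary covariates.  A positivity audit reports extreme scores.

Weights are re-estimated inside every bootstrap replicate so that
propensity-estimation uncertainty propagates into all intervals.

## Cognitive trajectories

MMSE over follow-up is modelled with a weighted linear mixed model:

    mmse_ij = b0 + th*arm_i + B(t_ij)'beta + arm_i * B(t_ij)'gamma
              + trial-month effects + u_i + e_ij,

with a random intercept `u_i ~ N(0, sigma_b^2)` per trial block and
`B(t) = [t, t^2, (t-8)_+^2]`, a quadratic truncated-power spline with a
knot at eight months that lets a rapid symptomatic change after
discontinuation differ from the long-run slope.  Blocks with baseline-only
data contribute through their t = 0 row; no imputation is used in the
primary analysis.  Change from baseline is the pure spline contrast
`B(t)'(beta + arm*gamma)`; the arm main effect (a baseline-level
imperfection of weighting, not an effect) and the trial-month terms cancel
in it, so no standardization over enrolment months is needed.

The random intercept is placed at the block level, not the patient level,
so that each block's IPTW weight multiplies one cluster's log-likelihood —
the weighting semantics under which an integer weight equals duplicating
the cluster.  Between-block correlation within a patient is then captured
by the cluster bootstrap rather than the likelihood.

Because no available mixed-model fitter accepts cluster-level analysis
weights (and, for the censoring-weighted sensitivity analysis,
observation-level weights inside clusters), the fit is implemented
in-package by profiled weighted maximum likelihood.  The random-intercept
structure keeps every quantity closed-form per cluster (Woodbury
identities), leaving a two-parameter optimization over the log variance
components evaluated from per-cluster sufficient statistics; the unit-
weight special case is verified against `statsmodels` MixedLM in the test
suite.  Start values split the OLS residual variance into between- and
within-cluster moments; bootstrap refits warm-start at the point
estimate's variance components.

Contrasts: the between-group difference at t months is
`change(continue, t) - change(discontinue, t)`, positive when
discontinuers decline more.  The delay in decline at t is the extra time
the continuer curve needs to reach the discontinuer level — found by
monthly-grid bracketing plus linear interpolation inside the bracketing
month, with a "not reached" signal if the level is never attained within
the horizon (72 months by default).

Inference uses a nonparametric cluster bootstrap (500 replicates by
default) resampling unique patients.  Confidence intervals are percentile
intervals; p-values use a normal-theory bootstrap-t when the replicate
distribution is near-symmetric (|skewness| < 0.5, an explicit
operationalization of the "depending on data symmetry" rule) and the
percentile method otherwise, floored at 1/B.  More than 5% failed
replicates aborts the run.

## Mortality

All-cause death is modelled on person-month data by weighted pooled
logistic regression — monthly death indicator on arm, follow-up month
(linear + quadratic), a linear arm-by-month interaction (the quadratic
interaction is configurable; the protocol specifies only "an interaction
between treatment and time"), and trial-month dummies.  Death
ascertainment is assumed registry-complete, so censoring is administrative
only; a death in the baseline month counts as an event at month one.
Absolute risk is `1 - prod(1 - h(m))`, computed per trial month and
averaged over the weighted empirical trial-month distribution; yearly risk
ratios are reported discontinuers versus continuers (the direction of the
published results) with cluster-bootstrap intervals.  With saturated time
dummies the model reproduces the weighted product-limit (Kaplan-Meier)
estimator exactly, which the tests verify against `lifelines`.  The
logistic solver is a compact Newton/IRLS routine (needed so the bootstrap
can refit from a cached design at interactive speed); it is checked against
`statsmodels` GLM to 1e-7.

## Sensitivity machinery

**IPCW.**  For dropout, a block is observed until its last visit (deaths
are treated like other dropouts here, a stated limitation of the source
design).  Stabilized inverse-probability-of-censoring weights use a pooled
logit of remaining-in-follow-up on baseline covariates, arm, and
linear+quadratic time (numerator: arm and time only), cumulated over
months and multiplied into the analysis weight at each visit time as an
observation-level weight.

**Delta-adjusted pattern mixture.**  Missing one-year outcomes (no visit
within +/-3 months of t = 12) are multiply imputed (M = 20 by default)
from the fitted trajectory model under MAR: fixed-effect prediction at 12
months plus a draw of the conditional random intercept given the block's
observed scores plus residual noise.  Parameter uncertainty in the fixed
effects is not re-drawn (improper imputation), acceptable because the
scan's role is a sensitivity direction, not primary inference.  Continuer
imputations are then penalised by delta (discontinuers unadjusted), the
weighted difference in mean one-year change is re-estimated per completed
dataset with a patient-clustered linearization variance, results are
pooled by Rubin's rules, and delta rises in 0.5-point steps until the
two-sided Wald test at the 5% level loses significance.  The Wald test is
used inside the scan (not the bootstrap) for tractability; the estimate is
exactly linear in delta with slope equal to the weighted continuer missing
fraction, which gives the closed-form oracle the tests exploit.

## Synthetic registry generator

The generator (`stoptrial.simdata`) emulates the data structure the
pipeline assumes: covariate margins resembling a French memory-clinic
cohort (age ~ 80.5 +/- 7.5 years, 65% women, baseline MMSE ~ 19 +/- 4.5
truncated to 10-30, psychotropic and cardiometabolic medication flags);
irregular consultations (jittered ~4.5-month gaps); integer MMSE scores
with measurement noise, rounding and 0-30 clipping, and a 5% missing-score
rate; per-visit loss to follow-up; and a constant monthly logit death
hazard with an age effect and an arm effect after stopping.

Three structural choices make the stacked sequential-trial IPTW estimand
*equal* the configured closed-form truth, so recovery tests are sharp:

1. **Stoppers stop at their first in-window consultation** (the natural
   response to a policy shock at window opening) **and next attend 7-12
   months later.**  The six-month ChEI-history criterion then makes each
   stopper eligible for exactly one trial — the one starting at the dated
   stop — so every discontinuer block's clock is aligned with its actual
   discontinuation and no stopper ever appears earlier as a contaminated
   continuer block.
2. **The continuer mean decline is linear in calendar time** (default
   -0.17 MMSE/month), so a continuer block's change from baseline is the
   same function of block time regardless of enrolment month.  The
   post-stop deficit delta(t) is expressed in the analysis spline basis in
   "paper_like" (delta(12) = 0.97, delta(48) = 1.81 points, mirroring the
   published effect sizes), making the outcome model exactly
   well-specified; a piecewise-linear "ramp" variant that the spline does
   not nest ships as a robustness probe.
3. **The stopping decision uses the *measured* score at the decision
   visit** — as a clinician would — plus time-invariant observed
   covariates.  Had it used the latent (noise-free) cognition, baseline
   measurement error would act as an unmeasurable confounder of change
   (regression to the mean) that no analysis of the observed data could
   remove.  As implemented, adjusting for the recorded baseline MMSE is
   exactly adjusting for the decision variable.

Decline heterogeneity is driven by a confounder index (the time-invariant
part of the propensity signal: age, institutionalisation, centre type,
education), so naive unweighted contrasts are biased.  `truth()` reports
the designed net unweighted bias, which combines the slope-confounding
term with an opposite-signed regression-to-the-mean term (stopping selects
on the baseline measurement noise); in "paper_like" the net designed bias
is about +0.44 points at one year.  `truth()` also returns the closed-form
differences and delays and mortality risks/risk ratios standardized over
the covariate distribution by a deterministic 200k-draw numerical average
with a fixed internal stream.

What the generator does *not* emulate — and hence what passing tests do
not establish about real registries: practice effects and other
non-monotone score dynamics, diagnosis-date uncertainty, treatment
restarts (the generator's stoppers stay stopped, matching the ITT
analysis but not pharmacy reality), secular calendar trends, inter-centre
heterogeneity, and genuinely unmeasured confounding of the stopping
decision.

## Numerical and operational choices

- Variance-component optimization: Nelder-Mead on (log sigma_b^2, log
  sigma_e^2), xatol 1e-4; an error is raised when no weighted cluster has
  two observations (variance components unidentifiable) or the optimizer
  fails.
- Duplicate (patient, month) visit rows are a hard error at screening;
  duplicated months inside a block keep the first value defensively.
- Weight truncation (symmetric percentile clipping) is available but off
  by default.
- Covariate adjustment in the outcome model (in addition to weighting) is
  available behind a flag and off by default, matching the
  weighting-only description of the source analyses.
- Mortality uses the extended covariate set (adds antihypertensive,
  antidiabetic, lipid-lowering flags), cognition the psychotropic set.
- All randomness flows from explicit integer seeds; reports are
  bit-reproducible from their manifest.

## Problem sizes in the shipped checks

The simulation checks run at sizes chosen for a single CPU: recovery uses
40 replicates of 3000 patients (Monte-Carlo SE about 0.03 points on the
mean 1-year difference) with the balance property evaluated at 40,000
patients (the SMD of a rare medication flag among a few hundred weighted
discontinuer blocks is sampling-noise-dominated at smaller sizes);
null-calibration coverage uses 100 replicates of 350 patients
with 60-resample bootstraps; the tipping oracle uses one 1200-patient
cohort with 10 imputations.  `scripts/acceptance.py` re-runs the same
studies at comparable sizes from a single command-line seed.

## Known limitations

- The block-level random intercept ignores that a patient's blocks share
  their latent level; the bootstrap covers the induced dependence for
  inference, but the point estimator forgoes the small efficiency gain a
  crossed design would give.
- The IPCW module treats death as censoring, as in the source design.
- The pattern-mixture scan tests each delta with a Wald test rather than
  the bootstrap; near the tipping point the two can disagree by roughly a
  grid step.
- The propensity model's trial-month terms are an approximation to the
  structurally decaying stopping pattern; this leaves trial month itself
  imbalanced (harmless for change-from-baseline contrasts, which do not
  depend on it) while covariate balance is verified directly.
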