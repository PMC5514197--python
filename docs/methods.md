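# Methods

`pulsepd` implements a two-step analysis of pulsatile endogenous hormone
concentration profiles (growth hormone, GH, is the worked case throughout):
a fully automated deconvolution of each individual 24 h profile, followed
by a nonlinear mixed-effects (NLME) population model whose pulse times are
fixed to the deconvolution output, plus a drug-effect layer used for
clinical-trial simulation and parameter recovery.

## 1. Structural model

The central compartment follows a turnover equation with a constant
zero-order basal input, pulsatile secretion and first-order elimination:

    dC/dt = k_in + S(t) * (1 + Effect(t)) - k_out * C,      C(t0) = A0

with `k_in = Baseline * k_out` so that `Baseline` is expressed in
concentration units (mU/L).  `A0` is the concentration at the first
scheduled sample; it absorbs secretion events that peaked before the
observation window, so no pre-window "phantom" pulses are introduced.

Secretion is a sum of events.  Two shapes are implemented:

* Gaussian (the default): `S_n(t) = exp(ln A_n - ((t - T_n)/w)^2 / 2)`,
  with peak rate `A_n` (mU/L/h), peak time `T_n` and a shared width `w`
  (h).  Although the reported unit of the population amplitude is mU/L,
  the quantity enters the turnover equation as a rate; `pulsepd` treats it
  as mU/L/h for dimensional consistency.
* Rational: `S_n(t) = A_n / (((t - T_n)/w)^exponent + 1)` with exponent 2
  or 4, retained as the structural alternative for model comparison.

### Evaluation paths

For Gaussian pulses without a drug effect the model has an exact closed
form: each pulse contributes an exponentially-modified-Gaussian response,
evaluated through the scaled complementary error function `erfcx` with a
per-element branch choice so that no placement of the pulse relative to
the window overflows or cancels catastrophically.  This is the default
path (fast, exact).

For the rational shape and for time-varying drug-effect modulation the
pulse responses are computed by numeric convolution on a uniformly refined
grid: trapezoid increments are propagated by the exact per-step decay
factor through a first-order linear recursion.  The refinement targets a
step of `width/20` (capped at a factor 600); against the stiff ODE oracle
(LSODA, rtol 1e-8, atol 1e-10, maximum step bounded by a third of the
pulse width) the relative error of this path is ~1e-4.  A bolus dose time
produces a jump in the effect; the segment straddling the jump uses the
left-limit of the integrand at its right endpoint, which integrates the
discontinuity exactly when the dose time lies on the grid.  Inside
optimizers the refinement factor is frozen at the typical width so that
the prediction stays smooth in the perturbed parameters.

### Covariates and random effects

Parameters are log-normally distributed across subjects,
`p_i = theta_p * (TBW_i / 44.7)^(exp_p) * exp(eta_p)`, with the power
covariate model on amplitude, width and baseline centered at the mean
total body water percentage (44.7%).  The amplitude of pulse `n`
additionally carries a per-pulse (between-occasion) effect:
`A_n = theta_A * cov * exp(eta_A + kappa_n)`.  Residual error is
proportional, `y = f * (1 + eps)`, `eps ~ N(0, sigma2)`.

The baseline-amplitude random-effect pair may share a 2x2 covariance
block; the covariance value is not available in the reference table, so simulation uses
zero covariance and estimation, when enabled, starts it at zero.

A circadian modulation of the amplitude is available either as a 24 h
cosine (acrophase parameter) or as a day/night step effect; the night
window is not specified in the source analysis and defaults to
23:00-07:00.

## 2. Step 1 - automated deconvolution

Each profile is the mean of duplicate samples on a regular 10-min grid,
weighted by the SEM computed from the assay CV model
(`sem = cv(mean) * mean / sqrt(n)`); means below the LLOQ (0.03 mU/L) are
excluded, not imputed.  The exact assay CV-vs-concentration function of
the original study is not published, so it is a caller-supplied function
(default: constant 5%).

The estimator is weighted nonlinear least squares over basal secretion,
half-life, initial concentration, a shared secretion width, and per-pulse
times and amplitudes (positivity via log transforms, pulse times bounded
to the observation window).  The pulse set is built by a phased,
fully-automated procedure:

1. *Scouting*: starting from a baseline-only fit, candidate pulses are
   inserted at the largest positive weighted residual (the first grid node
   is excluded: a pulse peaking there is indistinguishable from the
   initial concentration) and settled locally before a joint re-fit.  The
   shared width and half-life stay at their initial estimates (5 and 15
   min); they are not identifiable from an incomplete pulse train.  The
   phase is capped at 20 events.
2. *Release*: width and half-life become free; near-coincident pulses
   (closer than half a width) are merged; non-significant pulses are
   pruned.  Pulse significance is a Wald test of amplitude/SE against the
   normal reference at alpha = 0.05, with SEs from the Gauss-Newton
   Jacobian; numerically singular amplitude directions are treated as
   unsupported.
3. *Completion*: full insertion/re-fit/prune cycles until an inserted
   pulse fails its significance test, no positive residual remains, or the
   total budget of 60 insertions is exhausted.

The initial half-life estimate acts as a physiological anchor: the
weighted-RSS surface has nearly tied basins along a
basal/half-life/width ridge (smoother pulses with slower elimination can
fit 10-min data almost exactly as well), so during the analysis the
half-life is confined to a factor of two around the anchor, and the
constraint is lifted at the end only when the unconstrained fit improves
the weighted RSS by more than 6 points.  If the final weighted RSS remains
far above the noise floor the whole analysis is restarted from halved and
doubled anchors and the best kept.

**Known limitation - basal secretion.**  Under the default study
conditions (about fifteen 0.55 h-wide pulses per 24 h at 1.6 h intervals,
5% duplicate noise) the basal secretion rate is only weakly identifiable:
refitting synthetic profiles *from their true parameters* frequently
terminates at basal rates near zero or far above truth with a *better*
weighted RSS than the truth itself.  Pulse count (within +/-2) and
half-life (median error ~10%) are recovered reliably; basal secretion
recovery should not be expected to better than ~a factor of two per
profile, and group means should be interpreted accordingly.

Group summaries report the mean (sd) of each deconvolution scalar and
compare each group against the reference with a two-sided pooled-variance
(Student) two-group t test at p < 0.05.

## 3. Step 2 - population estimation

The marginal likelihood is approximated per subject by a Laplace
approximation around the joint conditional mode of that subject's random
effects (up to five etas, one kappa per pulse, plus an EA50 eta for dosed
subjects), with the residual variance evaluated at the conditional
predictions ("interaction").  The reported objective (OFV) is -2 log
likelihood with the `n log 2 pi` constant dropped; all other constants are
kept, so OFV differences between nested models with different random-effect
dimensions remain chi-square comparable.

The conditional modes are found by a damped Newton method whose Hessian
combines the exact second derivative of the data terms in the prediction
with the curvature of the multiplicative (log-scale) effects; Jacobian
columns for the linearly entering effects (baseline, initial
concentration, amplitude, every kappa) are analytic and only elimination
rate, width and drug potency use finite differences.  Steps are capped and
random effects bounded to |b| <= 15 (log scale).  The Laplace determinant
uses the Gauss-Newton form `J' V^-1 J + Omega^-1` evaluated at the final
mode.

The outer problem optimizes the free fixed effects and variances with a
Nelder-Mead simplex on transformed scales: logs for positive quantities,
`log(1 + Emax)` for the maximum drug effect (bounding it below at -1, full
inhibition).  Standard errors come from the central finite-difference
Hessian of the OFV (`cov = 2 H^-1`), mapped back by the delta method;
RSE% = 100 SE/|estimate|; CV% of a variance is `100 sqrt(exp(w2)-1)`; eta
shrinkage is `100 (1 - sd(EBE)/sqrt(w2))`; the condition number is the
eigenvalue ratio of the correlation matrix of the fixed-effect estimates.

Model selection follows the conventional likelihood-ratio rules: forward inclusion when the
OFV drops by more than the 5% chi-square critical value (3.84 at 1 df),
backward elimination unless removal raises the OFV by at least the 1%
critical value (6.6 at 1 df), and the Bayesian information criterion
(`OFV + k log n`) for non-nested structural comparisons such as the
Gaussian vs rational pulse shape.  Covariates are screened by the Pearson
correlation of each covariate against the eta EBEs with an |r| >= 0.5
threshold before formal testing as linear, power or exponential terms.

## 4. Drug effect, trial simulation and recovery

A hypothetical drug is a bolus with mono-exponential decay (default
half-life 6 h).  Its effect on secretion is a Hill function of the amount
remaining in the body, `Effect = Emax A^g / (EA50^g + A^g)`, multiplying
the secretion rate as `S(t) (1 + Effect(t))`; `Emax` ranges from -1 (full
inhibition) upward.

The default simulated trial is the reference proof-of-concept design:
five cohorts of eight subjects (placebo, 2.5, 5, 7.5, 10 mg dosed at 6 h),
a 0-24 h grid at 10-min spacing (145 samples per subject, 5800
observations), pulses at regular 1.57 h intervals (the mean pulse
interval), the full reference variability structure, a log-normal 10% CV
on the individual EA50 (`w2 = ln(1 + 0.1^2)`), and proportional residual
noise with simulated concentrations floored at zero.  The dose time of 6 h
and the inclusion of the A0 random effect follow the typical-individual
simulations (neither is stated explicitly for the trial).  The trial
simulator uses the same prediction engine as the estimator, so recovery
studies are free of discretization mismatch.

**Known limitation - the Hill coefficient.**  With 10-min sampling and the
reference variability structure, the likelihood in gamma is one-sidedly
flat: steep coefficients (roughly gamma > 8) are nearly indistinguishable,
and gamma trades off against the EA50 variance (a steeper population
dose-response with less potency spread resembles a shallower one with
more).  Recovered gamma values therefore scatter widely above the truth on
some simulated datasets while Emax and EA50 remain well determined.  For
this reason gamma is estimated on a logit scale bounded to (0, 12): Hill
coefficients beyond ~10 are not biologically meaningful for a drug effect,
are indistinguishable on this grid, and a near-step effect front also
degrades the numerical conditioning of the subject-level problems.  A
recovered gamma near the bound flags exactly this flat regime; users
fitting real data should then profile gamma or fix it.

Re-estimation fixes every structural parameter at its population value,
re-conditions all subject-level random effects, and fits two models: a
reference without any drug effect (re-estimating the residual variance
only) and the drug-effect model estimating Emax, EA50, gamma, the EA50
variance and the residual variance (4 extra df).  Starting values are
deliberately generic - a half-maximal inhibitor (Emax -0.5) with potency
at the low end of the dose range (EA50 2 mg, gamma 2) - so the recovery is
a genuine estimation exercise, not a refinement of the truth.

## 5. Synthetic data generator

The clinical profiles behind the original analysis are not public, so the
package ships a seeded generator that emulates them.  Group-level defaults
follow the reference deconvolution summaries (per-group mean and sd of
half-life, secretion width, basal secretion, amplitude and pulse
interval for normal-weight and upper/lower-body-obese groups before and
after weight loss).  Per subject, the generator draws these scalars from
truncated normal distributions, builds the pulse train from
truncated-normal inter-pulse intervals (floor 0.4 h), spreads per-pulse
amplitudes log-normally (sd(log) = 0.5 by default: the full reference
between-pulse variance would leave many events below the assay noise and
make count recovery meaningless as a check), draws the initial
concentration log-normally above the baseline level, and produces
duplicate assay replicates with multiplicative CV noise (default 5%)
followed by LLOQ censoring downstream.

The reference deconvolution amplitude (0.456 for normal weight) carries no
units; it is interpreted here as a peak secretion rate in mU/L per
*minute* (27.4 mU/L/h).  This is the only reading that reproduces
realistic GH profiles - pulse peaks of ~5-15 mU/L over a ~0.24 mU/L
trough and a 24 h mean near 8 mU/L; reading it as mU/L per hour would
bury the pulses under the baseline.

What the generator does *not* emulate: diurnal modulation of pulse
amplitude, assay CV varying with concentration, irregular or missing
sampling, occasion-to-occasion changes within a subject, and any
mechanistic feedback (GHRH/somatostatin).  Passing recovery tests on these
fixtures therefore demonstrates correctness of the estimation machinery
under the stated model, not robustness to model misspecification.

## 6. Problem sizes used in the shipped checks

The test suite runs deconvolution recovery on 20 generated profiles
(criterion: pulse count within +/-2 on at least 80% of profiles and a
median half-life error below 15%) and drug-effect recovery on a
three-cohort reduction of the default design (placebo/5/10 mg x 8,
3480 observations), which keeps the dosed/placebo contrast of the full
trial at half the computation.  The acceptance script simulates and
re-fits the full five-cohort design (5800 observations) and skips standard
errors there, which do not enter the reported quantities.
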