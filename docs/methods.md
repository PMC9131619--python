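# Methods

## The valuation problem

EQ-5D-5L describes a person's health by five attributes — mobility,
self-care, usual activities, pain/discomfort, anxiety/depression — each at
one of five severity levels, giving 5^5 = 3,125 profiles written as 5-digit
codes (`32512`).  A *value set* assigns each profile a number on the *pits
scale*: v(11111) = 1 (full health within the descriptive system) and
v(55555) = 0 (the pits state).  No time trade-off or dead-state evidence
enters, so the values carry no QALY interpretation.

`pitsval` estimates such value sets from two kinds of ordinal responses
collected in one sitting:

* **Paired comparison (PC).** The respondent chooses between health profile
  A and a constant comparator B = `24242`.
* **Case-2 best-worst scaling (BWS).** Shown a single profile, the
  respondent picks the *best* and the *worst* of its five attribute-levels.
  Best and worst enter the likelihood as two independent 5-way choices.

## Main-effect specification

Relative to a hypothetical ideal `00000`, a profile's disutility is the sum
of *ancillary* terms `eta_a` (the 0 to 1 step of each attribute, outside the
descriptive system) and *incremental* decrements `beta_{a,k}` (the level-k
to k+1 step, k = 1..4), twenty decrements in all.  Alternative codings:

* PC: utility difference uses only the incremental indicators; ancillary
  terms cancel.
* BWS: the alternative for attribute a at level l carries
  `sign * (eta_a + sum_{k<l} beta_{a,k})`, sign −1 for best, +1 for worst.

Each response is a multinomial logit choice with utilities
`lambda_t * x_j' theta`.  On the pits scale the decrements are normalized to
sum to 1; the raw sum is the log-odds of choosing 11111 over 55555 (the
*class logit*), and `logistic(class logit)` is a one-number summary of how
decisively a parameter set separates best from worst health.

Identification.  (i) Scale and coefficients are confounded, so the scale
function has no intercept (reference: a BWS-worst task extrapolated to
sequence 0, lambda = 1).  (ii) BWS likelihoods are invariant to adding a
constant to all five ancillary terms; we therefore anchor the smallest at
zero after estimation — the re-anchored vector is exactly the constrained
MLE by shift invariance, confirmed by a warm-started re-fit.

## Heteroskedasticity

The scale is an exponential function of task-level covariates only:

    lambda_t = exp(g1 * s_t + g2 * s_t^2 + g3 * 1[PC] + g4 * 1[BWS-best]),

with `s_t` the block-local task position divided by 25 (BWS tasks 1..25,
then PC tasks renumbered 1..24 after the dominance drop).  This encoding
makes a quadratic with coefficients (0.8419, −0.7427) peak at task
0.8419/(2 · 0.7427) · 25 ≈ 14 — `scale_peak_position` reports the rounded,
clamped position.  Respondent-level scale covariates are deliberately
excluded to keep heteroskedasticity distinct from scale heterogeneity.

The *interaction* model gives PC and BWS their own decrement sets under a
common scale function.  Here the PC task-type term g3 is **not identified**:
it multiplies only PC utilities, which have their own coefficient set, so
g3 trades off one-for-one against the overall scale of the PC decrements.
We exclude it; the PC scale shift is absorbed into the raw PC coefficients,
and the per-coefficient PC−BWS Wald tests are computed on pits-normalized
coefficients (delta method through the normalization), which are invariant
to that absorption.  Under a no-difference simulation these tests reject at
4–5% at the 5% level.

## Scale-adjusted latent classes

The SALC model mixes T taste classes (own `beta`, `eta`) and S scale
classes (utility multiplier `f_s`, reference class f = 1) with
covariate-driven memberships:

    L_i = sum_c sum_s pi_c(z_i) omega_s(w_i)
            prod_t P(y_it | beta_c, eta_c, f_s exp(gamma_s' z_t))

* Taste and scale memberships are independent softmaxes given covariates
  (the standard scale-adjusted latent class factorization); taste membership
  uses gender, age band, education band, chronic illness and VAS band, scale
  membership gender, age, education, the failed-dominant-task flag and
  perceived task difficulty.  Coefficients are reported as odds ratios.
* The task-level scale function is estimated per scale class, so the scale
  classes differ both by a constant factor and by their sequence/task-type
  response.
* A taste class whose probability of preferring 11111 over 55555 falls
  below 0.60 is flagged as a *garbage class* (responses unrelated to the
  attributes); the threshold separates a near-chance 0.55 from a decisive
  0.998 with margin and is configurable.

Estimation is by EM: the E-step computes posterior cell memberships; the
M-step runs a posterior-weighted joint quasi-Newton update of all choice
parameters (warm-started, capped iterations — a generalized EM step, so the
observed log-likelihood is monotone) and weighted softmax regressions for
the memberships.  Multistart (default 10) perturbs the heteroskedastic-logit
solution, including one structured start with a strong class plus a
near-noise class; each start runs a short EM and the best continues to
convergence (relative change < 1e-7).  Classes are then relabeled
canonically: taste classes by descending prob(11111 over 55555), scale
classes by descending factor, with GOM logits re-anchored.  A class whose
posterior mass falls below one respondent marks the start as degenerate.

Standard errors: CL/HCL/interaction use the observed information (central
difference Hessian of the analytic gradient, relative step 1e-5); the SALC
GOM block uses the outer product of per-respondent numerical scores of the
full mixture likelihood.  Information criteria use the number of choice
observations as n: BIC = −2 ll + p ln n, AIC = −2 ll + 2p,
CAIC = −2 ll + p (ln n + 1).

## Optimization details

Quasi-Newton (L-BFGS-B) from a zero start with analytic gradients,
projected-gradient tolerance 1e-7, at most 500 iterations.  Utilities are
evaluated with masked log-sum-exp; probabilities sum to one per task by
construction.  Degenerate inputs are rejected up front: malformed profile
codes, tasks without exactly one chosen row, collinear scale covariates
(named), missing respondent covariates (respondent and field named), a
non-positive decrement sum (no pits interpretation; flagged, raw returned).
Quantiles use linear interpolation (type 7); printed p-values of the form
"<0.001" are parsed as 0.0005, which is equivalent for threshold counts.

## Agreement statistics

Value tables are compared by Pearson correlation (Fisher-z 95% CI), Lin's
concordance correlation coefficient
`2 cov(x,y) / (var x + var y + (mean x − mean y)^2)` with the z-transform
CI, and the median and interquartile range of |x − y|.  |CCC| ≤ |r| always,
with equality only on the identity line.  CI constructions are approximate
and excluded from any numeric comparison surface.

## The synthetic-data generator

No respondent-level data are distributed with the package, so every
pipeline stage is exercised on a seeded synthetic study that mirrors the
study conditions the analysis assumes:

* 380 retained respondents plus 5 planted click-throughs; covariates drawn
  independently from the published sample marginals (52.1% male, age thirds
  0.326/0.308/0.366, education 0.137/0.518/0.345, 57.1% chronic illness,
  52.6% VAS < 70, 19% failed dominant task).
* A bundled synthetic 25-profile design (balanced orthogonal-array style,
  each level five times per attribute, no uniform-severity states, exactly
  one profile dominant against `24242`, placed last so the PC block stays
  1..24 after the drop).  It stands in for a study-specific orthogonal
  main-effects plan and carries no empirical content; any 25-profile file
  can be supplied instead.
* Two taste classes: the value-set class uses the published class-1 pits
  decrements at class logit 6.213 (prob 0.998), the garbage class the
  published class-2 decrements at logit 0.2161 (prob 0.554).  Ancillary
  truth is a small positive vector with one zero, (0.3, 0, 0.1, 0.5, 0.2):
  the published ancillary estimates are not available, and only the
  differences matter.  Scale classes (1.0, 0.5) — the published relative
  scale is unavailable, 0.5 is a clear but realistic separation —
  with the published heteroskedastic gamma (0.8419, −0.7427, −0.9930,
  0.2424) in both classes.
* Membership equations use the published odds ratios as log-odds slopes;
  intercepts are calibrated numerically (enumeration over the independent
  covariate cells) so the population garbage share is 0.29 and the
  low-scale share 0.59.
* The outcome of the dominant PC pair is forced to match the respondent's
  failed-dominant flag (that task is dropped before estimation, so this
  costs nothing in likelihood terms and makes the flag meaningful).

What it does not emulate: covariate correlations (independence is an
explicit simplification), panel non-response, response timing, within-task
best/worst dependence (best and worst draws are independent given the
class), or any attribute-interaction structure in preferences.  Passing
recovery tests therefore demonstrate correctness of the estimators under
the model's own assumptions, not robustness to real-data violations.

## Problem sizes used by the test suite

Parameter recovery runs the full pipeline at the study's size (n = 380 + 5,
74 analysed tasks each, 2×2 SALC, 10 starts) and asks for the value-set
class decrements within RMSE 0.015 on the pits scale, class shares within
±0.08, and the heteroskedastic signs.  Difference-test calibration uses 500
replicates of 30 homogeneous respondents.  Smaller fixtures (24–380
respondents) back the unit and property tests.

## Known limitations

* Values are on the pits scale only; no QALY anchoring or dead-state
  valuation is provided.
* Taste and scale remain partly confounded: when a weak-preference class
  concentrates in a low-scale class, the data constrain mainly the product
  of its class logit and the scale factor, so the class logit reported at
  the reference scale class can be overstated.  The value-set class, which
  spreads across scale classes, is unaffected in recovery experiments.
* The SALC surface fixes the number of classes per fit; no automatic
  selection over T and S beyond refitting with different settings.
* GOM standard errors come from an OPG approximation at the EM solution;
  they are adequate for odds-ratio magnitudes, not for fine-grained
  inference.
* No mixed (random-parameter) logit, rank-ordered logit, or Bayesian
  estimation.
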