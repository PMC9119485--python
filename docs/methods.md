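# Methods

## The observer model

On each estimation trial the participant infers the ball's final position
x from noisy sensory evidence s = x + ε, ε ~ N(0, σ²_evidence), under a
Gaussian prior centred on the target, x ~ N(x_target, σ²_prior).  The
posterior is Gaussian with mean

    x̂(s) = w·x_target + (1 − w)·s,      w = σ²_evidence / (σ²_evidence + σ²_prior),

and variance σ²_post = σ²_evidence σ²_prior / (σ²_evidence + σ²_prior).
The simulator draws the evidence sample, then the reported estimate from
N(x̂(s), σ²_post), then snaps it to the nearest option of the
veridical-centred response grid (ties to the lower index, positions
clamped to the screen).  A constant evidence shift x_shift relaxes the
assumption that evidence is centred exactly on the ball.

All positions are screen fractions in [0, 1]; pixels appear only at I/O.
The force → ball-velocity physics is not simulated: the ball position is
drawn directly as target + N(0, motor_noise_sd²), because every analysis
operates on positions and the mapping is monotone.  One relative-force
unit is identified with one screen width, so force errors in percentage
points equal position errors × 100.

## Slope-based estimation of prior weighting

Since E[x_estimate − x_ball | x_ball − x_target] = −w·(x_ball − x_target),
w is the negative regression slope of estimation error on performance
error.  Errors are z-scored within session (population-n denominator,
fixed for reproducibility) before a no-intercept fit, which makes the
slope equal to the correlation and removes the unit mismatch between
option-unit estimation errors and screen-fraction performance errors.
Two estimators are provided: independent per-session least squares (the
transparent oracle) and a REML random-slope mixed model with no fixed or
random intercept, pooled flat across all sessions (a per-participant
nesting option exists but is not the default, since each session is
treated as its own unit).  Estimates are not clipped to [0, 1] —
out-of-range values are flagged — because clipping would bias the recovery
study.

**Error-spread calibration.** Because the z-scored slope equals the
correlation, its expectation is w·sd(performance error)/sd(estimation
error).  The generator therefore calibrates the evidence noise as
σ²_evidence = m²(1 + w)/(2 − w) with m the motor noise, which makes the
marginal estimation-error sd equal to the performance-error sd — the
near-equality the task data themselves show (both ≈ 6.8% of screen
width) — so the estimator is neither attenuated nor inflated at any
generating w.  This calibration is the default for the recovery harness
and the cohort generator (`CohortConfig.calibrate_evidence_noise`).

**Parameter recovery.** For each w on a grid, sessions are simulated
through the full observer model (grid discretisation on) and re-estimated;
the harness reports the median and 95% quantile interval per grid point.
At the design size of 40 estimation trials and 2000 simulations per point
the absolute median bias stays below 0.05 everywhere (typically < 0.03;
the residual bias is the bounded discretisation effect, quantified rather
than assumed away).

## The hierarchical Bayesian model

The experimenter observes the ball position, not the participant's
evidence sample, so the likelihood marginalises over s:

    x_estimate ~ N(w·x_target + (1 − w)(x_ball + x_shift),
                   (1 − w)²σ²_evidence + σ²_post),

whose variance equals w(2 − w)σ²_prior.  (Conditioning on the ball with
only the posterior variance — i.e. treating the evidence as if it were the
ball — understates the predictive variance by (1 − w)²σ²_evidence and
inflates fitted σ's by ~40% on simulated data; the marginal form restores
calibration, and the two agree as σ_evidence → 0.)  Responses are treated
as continuous Gaussians even though recorded on a 12-option grid; a
discretised likelihood is out of scope, and the induced misfit (edge
clipping when the veridical option sits near the grid border) is
quantified with the posterior predictive check rather than modelled.

Each patient i contributes σ_prior(i), σ_evidence(i), drug effects
Δ_prior(i), Δ_evidence(i) applied additively in the atomoxetine session,
and x_shift(i).  Participant parameters are drawn from group-level
distributions: positive-truncated normals for the σ's, normals for the
rest.  Model variants fix one or both Δ's at zero (they are structurally
absent, not merely pinned); an additional diagnostic variant fixes x_shift
at zero for misspecification probes.

**Hyperpriors** (all screen-fraction units, weakly informative, every
constant overridable via `HyperPriorSpec`): group means of σ parameters ~
Normal(0, 0.2) truncated positive; group means of Δ's and x_shift ~
Normal(0, 0.1) — centred on zero, i.e. no drug effect or shift a priori;
all group sds ~ half-Normal(0, 0.1).  Scales are sized to the
screen-fraction data range.  Data enter in physical units (not z-scored)
so location/scale parameters stay interpretable.

**Sampler.** The posterior is explored with an adaptive
Metropolis-within-Gibbs scheme behind a log-density contract (any sampler
passing the R-hat and recovery suites is conformant).  Positive parameters
are sampled on the log scale with the change-of-variables term.  One sweep
comprises: (1) vectorised blocked random-walk updates of each
participant-level parameter kind for all participants at once (valid
because participants are conditionally independent given group
parameters); (2) an independence refresh for the Gaussian kinds proposing
from the group distribution (acceptance = likelihood ratio, which is near
1 exactly when shrinkage is strong and a random walk crawls);
(3) joint (σ, Δ) "ridge" moves that change log σ while holding σ + Δ fixed
(the atomoxetine session pins the sum, leaving the pair strongly
anticorrelated; the map is triangular with unit Jacobian); (4) funnel
moves per kind — a translation shifting the group mean and every
participant value together, and a scaling move rescaling the group sd and
the residuals jointly, whose participant-prior ratio cancels exactly
against the transformation Jacobian; (5) conjugate Gibbs updates for
Gaussian-kind group means and slice-sampling updates for positive-kind
group means and all group sds (their conditionals involve only prior
terms).  Step sizes adapt toward 0.44 acceptance during warmup only
(diminishing adaptation).  Defaults mirror the reference budget of 8
chains × 4000 iterations with 2000 warmup; chains are seeded from a single
`SeedSequence` and every seed is recorded.

Non-positive session σ's evaluate to −∞ (a rejected region, not an
exception).  Per-parameter rank-normalised split R-hat (maximum of bulk
and folded) and bulk effective sample size are reported with an overall
convergence flag (max R-hat < 1.01); poor convergence warns but never
raises.

**Information criteria.** WAIC is computed directly from the pointwise
log-likelihood (log pointwise predictive density minus the
sample-variance penalty, deviance scale, SE = √(n·var) of the pointwise
contributions); PSIS-LOO is delegated to arviz with per-point Pareto-k
diagnostics.  Pairwise differences use pointwise difference SEs.  On data
generated with nonzero drug effects on both precisions the full variant
wins both criteria against all three restrictions.

## Group-level inference

Continuous predictors are z-scored (sample sd) and categorical predictors
sum-to-zero coded (+1/−1), so coefficients are standardized betas; tests
are two-sided at α = .05, uncorrected by default (a Holm option exists).

- **Apathy regression**: prior weighting of the normative sessions
  (controls + patients on placebo) on apathy, group and their interaction,
  with the interquartile range of performance error as a covariate of no
  interest; 37 sessions and 5 parameters give 32 residual df.
- **Drug × LC CNR mixed model**: random intercept per participant
  (statsmodels MixedLM, REML).  Denominator dfs use the balanced-crossover
  within/between decomposition: terms involving the drug contrast are
  tested against the within-subject stratum (df = n − 2 = 15 at n = 17),
  other terms against the between-subject stratum (df = n − 3 = 14) — the
  Satterthwaite assignment, which coincides with heavier approximations
  for complete balanced data.  The per-participant Δw and its Pearson
  correlation with CNR (df = n − 2) are returned alongside.
- **Pitman-Morgan paired-variance test**: r = corr(x+y, x−y),
  t = r√(n−2)/√(1−r²) on n − 2 df.  Type-I error verified within
  [0.04, 0.06] over 10⁴ null simulations.
- **Johnson-Neyman**: the conditional slope b₁ + b₂z crosses significance
  where a quadratic in z vanishes; real roots are classified by direct
  evaluation (regions: all/none/between/outside, or above/below in the
  linear case) and mapped back to raw moderator units.  No real roots is
  a region, not an error.
- **JZS Bayes factors**: t tests use the default Cauchy prior on effect
  size (scale √2/2) via adaptive quadrature over the inverse-gamma mixing
  variable; correlations use the uniform (stretched-beta κ = 1) prior with
  the exact sampling density of r (Gaussian hypergeometric form).  Both
  verified against an independent implementation and a fixed-grid
  quadrature oracle to 4 significant figures.
- **Precision-term ANCOVA**: the two drug-effect precision terms
  (standardized by default; a raw mode exists) stack as a within-subject
  factor with Δw as between-subject covariate; the interaction F(1, n−2)
  is computed from nested least squares with subject fixed effects and
  equals the squared t of regressing the term difference on Δw.
- **Plausible values**: for each posterior draw, corr(Δσ_prior, Δw) and
  corr(Δσ_evidence, Δw) across participants, plus the per-draw
  difference, summarised by central 95% intervals — posterior uncertainty
  propagated into the downstream statistic.

## The synthetic cohort: what it does and does not emulate

The generator reproduces the study conditions: 17 patients × 2
counterbalanced sessions (drug order permuted in blocks of six) + 20
single-session controls; 4 blocks × 30 trials (20 basic + 10 estimation,
first 3 basic, no two consecutive estimation trials); effort targets at
35%/65% of maximum force crossed with reward on/off; veridical grid index
uniform on 3..10; apathy as rounded Gaussians clipped to the 0–42
instrument range; motor noise 0.068 screen fractions, chosen so the IQR of
force error is ≈ 9.2 percentage points; prior weighting centred at 0.45
(sd 0.18, clipped to [0.05, 0.95]); drug effects on w with sd 0.20.  The
couplings are standardized slopes: apathy → w at −0.35 and LC CNR → Δw at
−0.59 by default.  Coupling targets are met by construction in the latent
correlations; the sample correlation at n = 17 carries the usual
≈ ρ(1−ρ²)/(2n) finite-sample bias toward zero.

Not emulated: reward-feedback effects on behaviour, learning or
adaptation across trials, pharmacokinetics, response censoring at the grid
edge (clamped grids are flagged and kept), and any force→velocity
dynamics.  Passing tests therefore certify the estimators and inference
machinery under the stated generative assumptions, not robustness to
violations real data may show (e.g. non-Gaussian motor noise, drifting
priors).

## Numerical choices and problem sizes

- z-scoring uses the population denominator in the session estimator and
  the sample denominator in group statistics (each fixed and documented).
- Grid convention: the stated grid width is the outer-edge footprint of
  the option cells; spacing = width / n options; snapping ties go to the
  lower index; off-screen grids are translated minimally and flagged.
- Calibration windows slide one sample at a time (finest granularity).
- Reference sd in the CNR uses the n − 1 denominator.
- Recovery studies run 2000 simulations per grid point; hierarchical
  recovery and model selection use 17-participant cohorts with a reduced
  sampler budget (4 chains × 1500–2000 iterations, half warmup), and the
  fixture convergence check uses 8 × 6000 — sizes chosen as the smallest
  at which the checked properties are stable.
- The hierarchical recovery and model-selection experiments use the
  continuous-response mode: the continuous-Gaussian likelihood is exactly
  specified there, so interval coverage is interpretable; discretisation
  effects are assessed separately via the predictive checks.
- Degenerate inputs: zero-variance error series, single chains, empty
  ROIs, non-crossover patients and sub-3-trial sessions raise or warn
  with the offending unit named.

## Known limitations

The sampler is a Gibbs-style scheme tuned to this model family; posterior
geometry outside the tested regimes (e.g. extremely informative data with
near-zero group sds) may need longer chains, and R-hat slightly above 1.01
at default budgets indicates exactly that.  The mixed-model dfs are exact
only for complete two-session data (incomplete participants are excluded
with a warning).  WAIC uses the sample-variance penalty (n − 1), which
differs from some implementations' population variance by O(p/S).  The
inclusion-Bayes-factor machinery for mixed models is deliberately out of
scope; a BIC-difference approximation can be scripted from the reported
fits.
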