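# Methods

## The task and its coordinate system

The screen spans [−0.8, +0.8] (width 1.6). This is the unit system in which
the canonical spreads are stated: splash SD 0.096 (6% of screen width) or
0.24 (15%) around the hidden coin, prior SD 0.04 (2.5%) or 0.136 (8.5%)
around the screen centre. The prior mean μ_P is the screen centre, 0. A main
session is 4 blocks × 75 trials with the prior condition alternating between
blocks ("thrower" A/B) and the likelihood condition varying trial-wise;
a 100-trial calibration session shows splash sets with no prior structure,
the target being defined as the centre of the displayed splashes.

Two block-length details the design leaves open were fixed as follows.
75 trials cannot split evenly between two likelihood conditions, so blocks
alternate 38/37 and 37/38, making the session totals exactly 150/150.
Calibration-task splash centres are drawn uniformly on the central half of
the screen ([−0.4, +0.4]); a uniform draw avoids importing any prior
structure into the task that is meant to measure sensory noise alone.
Sampled positions are not clipped to the screen by default, so sample
moments equal the generating parameters exactly; a `clip_positions` mode
exists for display realism.

## Likelihood variance of the ideal observer

The evidence on a trial is the centroid of five splashes, so the ideal
observer's likelihood variance is the centroid variance σ_L² = splash_sd²/5
(0.096²/5 ≈ 0.001843 narrow, 0.24²/5 = 0.01152 wide). This is the package's
canonical `optimal_variance_mode="centroid"`. An alternative `"literal"`
mode instead treats the constants 0.09625 and 0.2425 as the likelihood
variances; it exists because those constants circulate as printed values for
this paradigm, but they are readable as typographically collapsed forms of
0.096²/5 and 0.24²/5, and the centroid interpretation is the one under which
the inversion identity returns the true prior variances. The normative
weights under the canonical mode are

| condition | σ_P² | σ_L² | sw_opt |
|---|---|---|---|
| PnLn | 0.0016 | 0.0018432 | 0.4647 |
| PnLw | 0.0016 | 0.01152 | 0.1220 |
| PwLn | 0.018496 | 0.0018432 | 0.9094 |
| PwLw | 0.018496 | 0.01152 | 0.6162 |

## Observer model

Each synthetic participant is a noisy Bayesian observer with *subjective*
variances. A latent standard-normal trait t (the individual-difference
dimension the group analysis targets) shifts the log subjective variances:

    log σ_P,subj²(c) = log σ_P²(c) + β_prior·t + η_P,   η_P ~ N(0, σ_b²)
    log σ_L,subj²(c) = log σ_L²(c) + β_lik·t  + η_L,   η_L ~ N(0, σ_b²)

with one jitter per variance family, shared across that family's two
conditions so the narrow/wide ratio stays at its true value (this also makes
the generating weight strictly monotone in the subjective prior SD).

Responses are generated as: perceived centroid = μ_L + Gaussian encoding
noise whose SD defaults to the observer's subjective centroid SD (so the
calibration-task estimator σ_SL² is estimating a quantity the generative
model actually contains); main-task response = posterior mean of prior and
perceived centroid under the subjective variances, plus motor noise
(SD 0.02); with probability 0.02 (lapse) the response is instead uniform
over the screen. Calibration-task responses are the perceived centroid plus
motor noise, with no prior integration and no lapse term — lapses model
inattention in the long main task; including them in the short calibration
task would contaminate the sensory-noise estimator that task exists to
provide. No response-noise model is dictated by the task itself; this
perceptual + motor + lapse decomposition is one admissible choice and is the
main caveat on generalising simulation results to real data.

The questionnaire score is a clipped, rounded lognormal map of the trait,
`cape_p = clip(round(20 + exp(a + b·t)), 20, 80)`, with (a, b) solved from
the target mean 27 and SD 6 of the excess over the scale floor — between the
two published cohort means for this instrument and reproducing its right
skew. Secondary covariates (negative/depressive subscales, spatial span,
age, gender) are synthetic plumbing with mild trait loadings, present so the
full battery has inputs.

### Default effect sizes

Defaults are β_prior = 0.10, β_lik = 0.04, σ_b = 0.55. The three latent
associations these imply are: trait–log σ_P,subj² ≈ 0.18, trait–log
σ_L,subj² ≈ 0.07, and trait–sensory-weight ≈ 0.08 (the weight is driven by
β_prior − β_lik, since both variances enter its odds ratio). All three
cannot simultaneously sit at 0.1: making both variance links equal would
null the weight link entirely. The chosen compromise keeps every link weakly
positive — uncertainty in both channels rises with the trait, and reliance
on likelihood rises with it too, dominated by the prior channel — which is
the qualitative structure the group layer is designed to detect.
`CohortSpec.for_sw_correlation(rho)` solves β_prior for an exact target
weight correlation (with β_lik = 0) when a calibrated effect is needed, and
`CohortSpec.null()` zeroes both slopes for type-I studies.

## Estimators and numerical choices

* The sensory-weight regression includes an intercept; with μ_P = 0 the
  prior term of the posterior mean is an intercept, and off-centre response
  bias is absorbed by it rather than leaking into the slope.
* The global weight pools all 300 main-task trials in one regression;
  per-condition and per-block weights filter the same table.
* The trial-wise weight is undefined when μ_L = μ_P; such trials are
  returned missing and excluded from the session variance. The raw value is
  clamped to ±50 before the logistic so near-degenerate trials cannot
  overflow. The session variance uses the conventional n−1 denominator.
* σ_SL² uses the population (1/nTrials) denominator, matching its defining
  formula; it is computed overall (n = 100) and per likelihood condition
  (n = 50).
* Condition-level σ_P² pairs each condition's weight with the calibration
  σ_SL² of the matching likelihood width — the only dimension the two tasks
  share.
* The inversion σ_P² = σ_SL²·sw/(1 − sw) is undefined at sw ≥ 1: such
  participant-conditions are returned missing rather than as negative or
  infinite variances, and sw ≤ 0 is clamped to variance 0 with a warning.
  Downstream correlations drop missing values listwise.
* Exclusions: |z| > 3 on mean calibration-task error first, then the same
  rule on mean main-task error among survivors; a zero-variance error
  vector flags nobody.
* Bootstrap CIs are percentile, resampling participants, 1000 replicates,
  seeded. The Bonferroni family is m = 4 (the four headline comparisons).
  The log transform of the questionnaire score uses the natural log; the
  base does not affect Pearson correlations.
* The Wilcoxon test versus the normative weight drops exact zeros and
  switches from the exact null to the continuity-corrected normal
  approximation above 25 non-zero differences.
* The condition ANOVA is a fixed-effects two-factor model with interaction
  on the participant × condition long table (no subject term); a
  repeated-measures variant is out of scope.
* The power computation uses the Fisher-z approximation with bias-corrected
  mean atanh(r) + r/(2(n−1)) and SD 1/√(n−3), root-found in continuous n
  and rounded up; at r = 0.10, power 0.80, α = 0.05 it returns n = 782.
  (The conventional "small effect" r = 0.10 is the input that reproduces
  that figure; a slightly larger pilot effect would give a smaller n.)

## What the simulations do and do not show

Problem sizes used in the test suite were chosen to make Monte-Carlo error
small relative to each assertion's tolerance: moment checks at 10⁴ draws,
benchmark-versus-simulation agreement at 10⁵ trials per condition,
manipulation checks on a 200-participant cohort, battery calibration over
200 null runs (n = 100) and 100 effect runs (n = 782).

Passing tests show that the estimators recover the generative model of
*this* observer family, that the group layer is calibrated (≈5% type I on
null cohorts) and powered as the Fisher-z analysis predicts, and that the
condition manipulations act in the designed directions. They do not show
that real participants follow the posterior-mean response rule, that real
response noise decomposes as perceptual + motor + lapse, or that the
questionnaire map reflects the instrument's psychometrics; those belong to
real data.

One recovery property deserves its own caveat: with the default noise
levels, a single 300-trial session estimates an individual's global weight
with an SE of roughly 0.04–0.05 (the encoding noise, scaled by the weight,
dominates in wide-likelihood cells, and rare uniform lapses add gross
outliers to the regression). Individual-level weights from one session are
therefore accurate to about ±0.1 at 95% confidence — fine for group-level
correlations at the studied sample sizes, but not for sharp per-person
claims; a tighter per-person band would need more trials or robust
(lapse-aware) fitting, which the closed-form pipeline deliberately avoids.
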