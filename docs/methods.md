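# Methods

This note documents the models, the synthetic-data generator, the
estimation procedure and the numerical choices in `rlwm_lba`, in the
order a reader would meet them in the pipeline.

## Task model

The task is a deterministic stimulus-action association task: 11 blocks,
each with a set of 2-5 stimuli (default composition
`[2,2,3,3,3,4,4,4,5,5,4]`), three response keys, and reward 1 iff the
chosen action matches the stimulus's assigned action.  Within a block a
stimulus is presented repeatedly in pseudo-random order (no immediate
repetition while at least two stimuli are still active) until it has
been answered correctly on at least 4 of its last 5 presentations, with
a floor of 9 and a ceiling of 15 presentations.  The criterion is
applied per stimulus; it retires a stimulus at the *first* presentation
count >= 9 at which the window condition holds (a responder that becomes
correct from presentation 8 onward therefore retires a stimulus at
presentation 11: presentations 7-11 contain four corrects).

Derived covariates: `presentation_index` (iteration of the stimulus
within its block) and `delay` (trials of any stimulus since the last
correct response to this stimulus; missing when no prior correct exists).
The EEG analysis set is the correct, non-first presentations.

## Cognitive model (RLWM)

Two modules maintain stimulus-action values `Q` in [0,1], initialized at
1/3:

* **RL**: delta rule, `Q <- Q + a_eff (r - Q)` with `a_eff = alpha_rl`
  for non-negative prediction errors and `(1 - bias) alpha_rl` for
  negative ones (neglect of negative feedback).
* **WM**: the same rule with learning rate 1 (one-shot storage, same
  bias), plus a per-trial decay of *every* entry toward 1/3 at rate
  `phi`, applied after the current trial's update.

Each module emits a softmax policy with fixed sensitivity `beta`; the
mixed policy is `pi = W p_wm + (1 - W) p_rl` with
`W = rho * min(1, C / n_s)` (`C` in (2,5) is WM capacity, `n_s` the set
size).  We read the mixture as WM-weighted-by-`W` plus RL-weighted-by-
`(1-W)`; a formulation that multiplies the WM policy by both weights
would make the mixture degenerate and contradict the mixture's purpose.

Block-level uncertainty is the Shannon entropy (bits) of the policy
averaged over the block's stimuli, computed *before* the current
stimulus is encoded: `H_prior = -sum_i mu_i log2 mu_i`,
`mu = mean_s pi(.|s)`, floored at `1e-6` bits so drift rates stay
finite.

**Softmax sensitivity.** `beta_rl = beta_wm = 10` by default
(config-exposed).  Choice stochasticity is carried by the accumulator
race, so `beta` only shapes how Q-value magnitudes pass into the policy
and the entropy.  At much larger values (e.g. 50) both module policies
collapse to argmax(Q); the two modules then agree on almost every trial
and the mixture weight `W` (hence `rho` and `C`), and the learning rate
above ~0.05, lose essentially all likelihood curvature — profile checks
show under half a nat across the whole `rho` range.  At `beta = 10`
value differences remain graded, the parameters are identifiable, and
simulated learning curves still reach realistic asymptotes.

## Choice model (LBA)

Three independent accumulators start uniformly in `[0, A]`, rise
linearly with slope drawn from `Normal(v_a, s)`, and the first to reach
`b = A + k` determines choice and RT (`rt = tau + passage time`).  Drift
rates are `v_a = eta_t * pi_a / H_prior`: confident low-uncertainty
policies accumulate fast.  In the neurally informed variant
`eta_t = eta + z(CPP slope) * beta_slope`, floored at `eta_min = 0.01`;
the baseline model is `beta_slope = 0`.

Conventions: `s` is fixed at 1.0 (the standard identifiability
convention; config-exposed).  Trials on which all three sampled slopes
are non-positive are redrawn, and the defective density is renormalized
by `P(at least one positive slope)` so that simulator and likelihood
agree exactly; the densities then integrate to 1 over (choice, rt).
The 7 s response window clips fewer than 1% of simulated RTs and is
ignored in the likelihood (no censoring term).  Log-densities are
floored at `log(1e-300)`.  The compiled kernel uses `erfc` for normal
tail probabilities; plain `erf` saturates and loses the tail mass that
the race's slow-RT trials live on.

## Synthetic cohort

Subject parameters are drawn from normal distributions on the
unconstrained scale and mapped through the same transforms the fitting
uses (probit for unit-interval parameters and `tau`; `2 + 3 Phi(x)` for
`C`; `exp` for `k`, `A`, `eta`).  Default group means/sds describe a
population with slow RL learning (~0.07), moderate negative-feedback
neglect, WM decay ~0.3, high WM propensity (~0.84), capacity ~3.9,
`A ~ 0.8`, `k ~ 0.5`, `eta ~ 2.7`, `tau ~ 0.3 s` — chosen once as
plausible for this task family and used as the package's study
conditions.  A per-trial standard-normal `cpp_slope_z` is always drawn
and recorded; it enters generation only when `beta_slope_true != 0`.

### Synthetic EEG

Per included trial a continuous signal is synthesized from -700 ms
(stimulus lock context) to 700 ms past the response, and both epochs are
cut from it, so stimulus components bleed into response-locked windows
exactly as overlapping potentials do in recorded data.  Components:

* **CPP**: a linear ramp toward the response at rate
  `0.07 + 0.05 z(drift)` uV/ms (floored at 0.005), starting
  `min(rt, 600 ms)` before the response, peaking at the response and
  falling back over 200 ms; spatial Gaussian (sigma 1.0 grid units)
  centered on CPz.  Peak amplitudes are deliberately large relative to
  recorded CPPs: the per-trial slope is read from just two landmark
  samples, so the buildup-rate gain must clear the AR(1) noise for the
  slope to track drift (r > 0.5) at realistic noise amplitude.
* **300 ms fronto-central negativity** (sigma 50 ms) with amplitude
  `-(2.5 z(Q_RL) + 1.5 z(delay))` uV, centered on FCz.
* **540 ms parietal positivity** (sigma 60 ms) with amplitude
  `+2.5 z(set size)` uV, centered on POz.
* **Noise**: AR(1) per channel, lag-one coefficient 0.95, stationary sd
  8 uV.

The generator reproduces the stimulus/response overlap confound: the
CPP's bleed into stimulus-locked latencies spatially dominates the
delay and set-size t-maps (deconvolution controls are out of scope), so
sign recovery is evaluated at the injected site and full topographic
localization at the component's characteristic latency for the Q_RL and
drift maps.  Channel geometry is an idealized 64-label 10/20-style grid
with 2-D coordinates — adequate for Gaussian weighting and neighborhood
checks, not a head model.  What the generator does *not* emulate: 1/f
noise, artifacts (blinks, muscle), volume-conduction mixing beyond the
Gaussian kernels, or stimulus-onset jitter.  Passing tests therefore
show that the statistics recover structure of this kind at these SNRs,
not that they are robust to every property of recorded EEG.

## Estimation

The hierarchy places `N(mu_j, sigma_j)` priors on each subject's
unconstrained parameters.  Group-mean priors follow the model's
published formulation (e.g. `mu_alpha ~ N(-3, 3)`); the capacity prior
is stated on the natural 2-5 scale with center 3 and is mapped through
the inverse transform (center `Phi^{-1}(1/3) ~ -0.43`), since an
unconstrained center of 3 would place the prior mass on the `C = 5`
boundary.  Group sds have Exponential(0.1) priors; `beta_slope` has a
N(0, 1) prior.

The desk-scale estimator (`mode="map"`) is empirical-Bayes flavored:

1. per-subject MAP by multi-start L-BFGS-B (5 starts, box bounds
   [-10, 10] on the unconstrained scale, ftol 1e-8), starting wide
   (`sigma = 2`) so the first pass is likelihood-driven;
2. conjugate update of each group mean given the subject modes, and a
   moment update of each group sd clipped to [0.25, 1.5] (the floor
   prevents hierarchical collapse of weakly identified parameters, the
   cap keeps pooling active);
3. two more alternations of 1-2;
4. a Laplace (Gaussian) approximation at each subject's mode:
   finite-difference Hessian, eigenvalue-clipped covariance, draws
   truncated at 2.5 sd (the quadratic approximation otherwise overshoots
   into zero-density regions such as `tau` above the fastest RT).  Draw
   noise is seeded per subject independently of the model tag, so
   nested models share common random numbers and their pointwise
   log-likelihood differences have small Monte-Carlo variance.

The group-level `beta_slope` summary pools the per-subject modes with
their Laplace standard errors by DerSimonian-Laird random-effects
meta-analysis (mean, SE, 95% interval).  `vi`/`mcmc` modes are not
provided; the log-posterior is a single shared definition, so adding a
sampler would not change the model.

Shrinkage note: correlations between true and recovered parameters are
essentially invariant to the hierarchical shrinkage (a common linear
map), so recovery r reflects per-subject likelihood information, not
the pooling strength.

## Model comparison

Pointwise expected log predictive density is estimated by PSIS-LOO
(Pareto-smoothed importance sampling) from the Laplace log-likelihood
draws, with a WAIC-style fallback if smoothing fails and a plug-in
fallback for fits with fewer than 10 draws; the method used is recorded
in the output.  `elpd_diff` is reported as better minus worse with
`se_diff = sqrt(n * var(pointwise differences))`.

## ERP statistics

Per subject, each electrode x time-point series is regressed by OLS on
z-scored covariates (within-subject z, sd with n-1): set size, delay and
chosen-option Q_RL for stimulus-locked epochs (missing-delay trials are
dropped; a zero-variance predictor is zeroed and flagged), drift rate
for response-locked epochs.  Group inference is the 20% trimmed mean
with Yuen's one-sample t (winsorized variance, `df = h - 1`,
`h = n - 2 floor(0.2 n)`); a zero winsorized variance with a nonzero
trimmed mean is treated as maximally significant.  The Bonferroni
threshold is `alpha / (E * T * P)` with `alpha = 0.05` and `P` counting
all estimated maps including the intercept (stimulus lock: 4; response
lock: 2); with 64 electrodes and 716 time points the stimulus-locked
threshold is 2.73e-07 — the formula, not any printed shortcut, is
authoritative, and the output records both the product and the
threshold.

CPP slope: amplitudes at the nearest samples to -200 and -50 ms on CPz,
divided by the actual landmark separation (nominally 150 ms; the
nearest-sample error is <1 ms at 512 Hz).  Quartiles are rank-based
within subject x set size with stable ties.  The slope regression
`cpp_slope ~ q_rl_quartile * set_size + q_wm_quartile * set_size` uses
numeric quartiles, categorical set size, per-subject intercepts, and
cluster-robust (by subject) standard errors; per-set-size simple slopes
with 95% intervals are reported.

## Problem sizes

Default analyses run at the full task design (11 blocks, ~390 trials
per subject).  Cohort sizes and conditions used by the validation
suites are the package's own choices: 30 subjects for parameter
recovery; 20 subjects with `beta_slope_true = 0.094` for the
slope-coefficient recovery; 10 subjects for the model-comparison
direction checks, with a strongly slope-informative generator
(`beta_slope_true = 0.25`) for the positive condition — at desk-scale
cohort sizes the predictive gain from a 0.094 coefficient is real but
sits near its own standard error, which is a sample-size statement,
not a model one; and reduced EEG grids (8-19 channels at 128 Hz) for
the mass-univariate simulations.  The quartile-regression dissociation
(RL association rising, WM falling with load) is demonstrated on a
WM-dominant, strongly decaying cohort (`rho ~ 0.96`, `phi ~ 0.5`,
`C ~ 3`, near published estimates for this task family); under the
default moderate-WM cohort the within-block entropy decline at low
load is large enough that the Q_RL association peaks at set size 2
instead.  Full-scale EEG (64 channels, 512 Hz, 716 samples) is
generated per subject on demand.

## Known limitations

* The estimator is a mode-based approximation; posterior uncertainty
  comes from a truncated Laplace approximation, and PSIS diagnostics
  (Pareto k) should be inspected before trusting close ELPD calls.
* WM capacity `C` is weakly identified at any softmax sensitivity in
  this design (the likelihood is flat once `C >= n_s` for most blocks);
  rank-order recovery is the realistic expectation.
* The RT likelihood ignores deadline censoring and models errors with
  the same drift construction as correct responses; the underlying race
  model is known to capture incorrect-response RTs imperfectly.
* The EEG generator's component amplitudes are stylized (see above);
  absolute effect sizes in microvolts are not calibrated to a recorded
  dataset.
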