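# Methods

## The task and the two models

An observer explores a weak one-dimensional elastic force field and reports
where its center (or edge) lies. Because forces below the detection
threshold `F_th` are imperceptible, there is a blind region around the true
center whose half-width is `F_th / K` for a spring of stiffness `K`. All
model math uses a field-centered frame (origin at the true center, positive
rightward) and SI units; centimeters appear only in human-facing output.

**Bisection model.** The center estimate is the weighted midpoint of the
positions where the force reaches threshold. Bias and within-participant
variability for a bilateral field:

```
mu_x      = (1 - w)(-F_th/K_left) + w (F_th/K_right)
sigma_x^2 = (1-w)^2 (sigma_Fth^2/K_left^2 + sigma_P^2)
          +  w^2    (sigma_Fth^2/K_right^2 + sigma_P^2)
```

with `w` fixed at 1/2 (device at the body midline). When the two visual
feedback conditions are fitted jointly the positional variance term becomes
`2 k sigma_P_fp^2 + (1-k) 2 sigma_P_fa^2`, where the switch `k` is 1 with
feedback and 0 without; feedback is assumed to affect only positional
noise. A unilateral field reduces to `mu_x = F_th/K` (signed toward the
spring) and `sigma_x^2 = sigma_F^2/K^2 + sigma_P^2`.

**Stiffness model.** Perception of force follows a Stevens power law
`F~ = alpha (F - F_th)^beta` (`beta = 0.8` from prior measurements; `alpha`
cancels from every prediction and defaults to 1). Estimating stiffness as
the local slope of the perceived force and extrapolating to zero gives the
edge estimate `x~ = x - (x - x0)/beta` for a probe at `x`, where `x0` is the
threshold position. A bilateral estimate averages the two sides. For
`beta = 1` this is identical to bisection; for `beta < 1` it predicts
strictly smaller biases, shrinking with probe depth. Probes in the
sub-threshold region raise an error — the extrapolation is undefined where
nothing is felt.

**Adjudication.** Because the stiffness model's prediction depends on the
unknown probe position, adjudication uses prediction *bands*: the bisection
bias is computed at the two ends of the literature threshold range
0.05–0.1 N; measured |bias| per condition is classified below/inside/above
that band (Experiment 1 summaries are first averaged across feedback
conditions). Systematically sub-band biases favor the stiffness account;
in-band biases favor bisection, after which only the bisection model is
fitted. The stiffness band, when requested, is the envelope of the
extrapolation bias over an equal-force probe sweep from just above `F_th`
to the force at the linear field edge (±6 cm, the only probing assumption
with a stated geometric motivation).

## Fitting

The objective sums squared bias and SD residuals over conditions,
`SS = Σ (x_i - mu_i)^2 + (s_i - sigma_i)^2`, both in meters (mixing a first
and a second moment in one SS is a deliberate property of the procedure,
kept as stated). Experiment 1 fits (F_th, sigma_Fth, sigma_P_fp,
sigma_P_fa) to 14 conditions; Experiment 2 fits (F_th, sigma_F, sigma_P) to
6. Goodness of fit is the coefficient of determination over the
concatenated (bias, SD) vector — the same vector the SS minimizes; its
numerical value on the original study's data cannot be checked here because
the raw summaries were published only graphically.

Numerical choices:

* deterministic multi-start: a fixed grid of starts spanning F_th ∈
  [0.01, 0.3] N, threshold noise ∈ [0.01, 0.15] N, positional noise ∈
  [0, 3] cm; Powell's derivative-free method under nonnegativity box bounds
  (`xtol 1e-10`, `ftol 1e-12`); ties across starts broken by the lowest
  fitted F_th;
* the predictions are exactly linear in the parameter vector, so the data
  are rescaled to a reference magnitude (~1 cm) before optimization and the
  parameters rescaled back — fits are invariant to the input length unit;
* a fit where no start converges is returned flagged (`converged=False`),
  never silently.

Noiseless round-trip recovery (generate 14 or 6 condition predictions from
a parameter set, fit them back) recovers every parameter to ~1e-8 relative
error, far inside the 0.1% bar the self-consistency tests assert.

## Synthetic experiments

The generator reproduces the two designs exactly: per condition, field
centers drawn uniformly in three regions (−3..−1, −1..1, 1..3 cm from the
workspace middle) and start distances uniform in 1–3 cm — used on both
sides of the center in the bilateral design (mirror balance), and always on
the force-free side of the edge in the unilateral one. Counts are exact for
every seed: 84 and 36 trials per participant. Design randomization and
endpoint noise run on independent substreams of the participant seed
(numpy `SeedSequence.spawn`), so the same designs can be replayed under
different generative models.

Endpoints are drawn as `center + model bias + Normal(0, model SD)` from
either generative model (the stiffness generator uses the equal-force
extrapolation estimate plus positional noise). Exploration trajectories are
not constrained by the models, so a minimal kinematic stand-in is used: a
cosine around the true center whose amplitude decays exponentially while
the oscillation midline slides toward the endpoint, sampled at 250 Hz.
Duration and oscillation frequency default to the observed medians
(10.9 s / 11.1 direction changes bilateral; 8.5 s / 8.2 unilateral); the
amplitude is inflated when needed so the hand crosses the center for at
least ~1.25 periods, guaranteeing ≥2 force zero-crossings in bilateral
trials, and the final 150 ms rest exactly at the endpoint so the
last-100-ms endpoint definition is recovered to machine precision. Forces
follow the trial's field law exactly (repulsive bilateral, attractive
unilateral); the device's high-frequency-noise events are abstracted into a
boolean quality flag with injectable flagged epochs. No grip-force channel,
force-rendering error, or closed-loop device dynamics are simulated — so
passing tests validate the analysis chain and the models' internal
consistency, not robustness to hardware artifacts.

## Preprocessing

* Endpoint: mean position over the final 100 ms (25 samples at 250 Hz).
* Bilateral trials are referenced to the per-trial mean of the force
  zero-crossings (linear interpolation of position against force between
  the samples bracketing each sign change); unilateral trials to the
  designed center, since their force is zero on an entire side. On
  noiseless synthetic data the unilateral chain is exact; the bilateral
  chain carries a ≤ ~4e-5 m residual because a crossing falling between two
  samples of an *asymmetric* field spans the stiffness kink, which a
  field-agnostic linear interpolation cannot represent. This mirrors the
  measurement situation itself and is two orders of magnitude below the
  biases of interest.
* Outlier rule 1: a quality-flag run strictly longer than 0.5 s rejects the
  trial (exactly 0.5 s is kept). Rule 2: one leave-one-out pass per
  condition; trial `i` is rejected iff `|x_i − mean_{−i}| > 5 SD_{−i}`
  (sample SD, n−1). The pass is single, not iterated — iteration would
  change rejection counts; re-running it on the kept trials rejects nothing
  new. Degenerate case: if the other trials are identical (SD 0), any
  differing trial is rejected. Rule 2 needs ≥3 trials.
* Summaries: per-condition bias = mean signed error, SD with n−1; group
  level = unweighted means across participants, SE = SD/√n. Group summaries
  are what the fit consumes.

## Problem sizes used by the test suite

Self-consistency fits use the designs' native sizes (14 and 6 conditions).
Monte-Carlo generative consistency uses 10^4 endpoint draws per condition
(3% tolerance); cohort-level parameter recovery uses 100 replicate cohorts
of 12 simulated participants each, fitted end to end, asserting a median
absolute force-threshold error ≤ 0.02 N (measured: ~0.003 N).

A finite-sample property of the procedure worth knowing: the per-condition
SD is a sample SD over 6 trials, whose expectation is `c4(6) σ ≈ 0.95 σ`
for normal endpoints, and the nonlinear joint fit adds a further small
downward noise-induced bias — so the recovered noise parameters are
systematically shrunk by ~5–10% at the study's cohort size (the force
threshold, identified by the biases, is unaffected). The recovery tests
assert the shrinkage-corrected expectation rather than strict
unbiasedness.

## Known limitations

* The stiffness model is used for prediction bands and as an endpoint
  generator only; it is never fitted to data (the adjudication procedure
  stops at the band comparison).
* The repeated-measures ANOVA layer is out of scope; group summaries are
  exported as CSV for any external stats tool.
* The trajectory generator matches printed movement medians, not real
  kinematics; quantities derived from fine trajectory structure (velocity
  profiles, inter-reversal distances) should not be read off it.
* `w` is stored but fixed at 1/2 throughout; freeing it is untested
  territory.
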