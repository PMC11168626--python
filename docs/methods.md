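# Methods

This note records the modelling assumptions, parameter choices, and
numerical decisions behind `reachvigor`, and what the synthetic-data tests
do and do not establish about real data.

## Effective mass (`biomech`)

The arm is a planar two-link chain (upper arm; forearm+hand) with an
optional point mass at the hand, supported against gravity.  The scalar
inertia felt at the hand for an acceleration in direction û is
`‖M û‖` with `M = J⁻ᵀ I(θ) J⁻¹`, where `J` is the two-link Jacobian and
`I(θ)` the joint-space inertia matrix.

* **Inertia of the loaded forearm.**  The forearm+hand segment and the
  added point mass are combined into one rigid body: combined mass
  `m₂ + p`, mass-weighted centroid `r₂₂`, and centroidal inertia obtained
  by the parallel-axis theorem.  This is algebraically identical to
  summing the segment and point-mass Lagrangian terms; writing the matrix
  with `r₂₂` but an untransferred centroidal inertia would break
  consistency with rigid-body dynamics, which the test suite checks
  against a kinetic-energy/inverse-dynamics oracle at 1e-6 relative.
* **Anthropometry.**  Segment masses, lengths, centroids and radii of
  gyration come from Winter's regression table (upper-arm mass 0.028·M,
  length 0.186·H; forearm+hand mass 0.022·M; etc.), exposed as an
  overridable coefficient dictionary.  The reach point is the hand centre
  (forearm length + half hand length from the elbow), matching a handle
  held in the palm.
* **Evaluation posture.**  Effective mass varies along the reach; it is
  evaluated at the inverse-kinematics posture of the reach midpoint (5 cm
  from home) for each target direction, and averaged over the four
  diagonal directions (45°, 135°, 225°, 315°).  The home circle sits
  0.25 m anterior of the shoulder by default — a typical seating geometry
  for a planar manipulandum; both the home position and the evaluation
  distance are arguments.  With cohort-average anthropometry this yields a
  no-load mean effective mass near 2.2–2.4 kg.
* Downstream analyses default to the packaged cohort-mean effective-mass
  table rather than recomputed values, so table reproduction does not
  depend on anthropometric guesses.

## Metabolic model (`metabolics`)

* Gas flows are standardised to mL/s so Brockway power is in watts.
* The moving-time normalisation removes resting expenditure during the
  non-moving fraction of a block and attributes the remainder to movement:
  `ė_m = (ė_measured·T_trial − ė_rest·(T_trial − T_m)) / T_m`.  Steady
  state is taken as the trailing 180 s of a block.
* The rate model `a + b·mⁱ/t_mʲ` is fit by nonlinear least squares on
  untransformed watts (matching the scale on which the residual variance
  is reported); a log-scale fit is not the default.  The alternative form
  `a·mᵏ + …` tests a mass-dependent resting cost.  AIC uses the Gaussian
  likelihood with the residual variance profiled out, constants included:
  `n·ln(2π·RSS/n) + n + 2(p+1)`.
* The default fitting unit is condition means of subject averages
  (4 masses × 6 speed windows = 24 rows); raw block rows work identically.
* The optimal duration uses the closed form
  `t* = ((j−1)·b·mⁱ/a)^(1/j)` (validated to lie within (0.1, 3.0) s, which
  brackets all plausible reach optima); the tests verify agreement with a
  dense grid minimisation.  Degenerate inputs (`b = 0` or `j ≤ 1`) raise
  rather than returning a boundary value.
* Bootstrap: case resampling of rows with replacement, refit warm-started
  at the full-data estimates, percentile 2.5/97.5 intervals; replicates
  whose fit fails or whose optimum leaves the bracket are skipped and
  counted.  Deterministic given a seed.

## Kinematics (`kinematics`)

* Filtering is a zero-phase (forward–backward) fourth-order Butterworth at
  10 Hz.  Zero-phase filtering is chosen so that filter lag cannot bias
  onset times.
* Differentiation uses the five-point central stencil (exact to quartic
  polynomials), with one-sided five-point stencils at the first and last
  two samples; acceleration is the stencil applied twice.
* Movement segmentation thresholds the moving-window standard deviation of
  speed (0.0006 m/s) and of acceleration magnitude (0.0075 m/s²), window
  50 ms.  Onset uses a centred window (first sample after target onset
  where both exceed threshold); offset uses a forward-looking window
  (first sample after peak speed where both settle and stay settled for a
  full window) — the forward-looking variant removes the half-window lag a
  centred window imposes at movement end.  Both variability signals must
  be below threshold for offset: the speed criterion alone dips spuriously
  at peak velocity where the profile is momentarily flat.  On noise-free
  minimum-jerk reaches of 0.2–1.4 s the segmentation error is within
  ±25 ms (≤ 5 samples); a windowed-variability detector has irreducible
  edge effects of a few samples, so sample-exact agreement is not claimed.
* These thresholds presuppose encoder-level measurement noise: position
  noise above roughly 20 µm rms lifts the filtered acceleration-
  variability floor above the settle threshold and the offset cannot
  latch.  The synthetic generator therefore defaults to 10 µm noise.
* "Reaction velocity" (used by the outlier rules) is the tangential speed
  at detected onset.
* Angular error is the signed angle (degrees, counterclockwise positive)
  between the home→endpoint ray and the home→target ray, evaluated at
  movement end (offset, or maximum excursion for out-and-back trials).
* Outlier rules: the prescribed-speed ruleset uses absolute bounds
  (endpoint error > 10 cm, duration outside [0.2, 2] s, reaction time
  > 0.5 s, |angular error| > 50°); the self-paced ruleset removes trials
  outside 1.5×IQR fences per subject×condition on duration, reaction
  time, reaction velocity and angular error, plus maximum excursion
  > 14 cm for the stop-at-target experiments only.

## Speed–accuracy model (`accuracy`)

* Success criteria use strict inequalities ("less than") throughout.
* The arc criterion applies the full 7° width to the magnitude of the
  angular error, following the verbal rule; the geometrically tighter
  ±3.5° reading is available via `angular_limit_deg=3.5`.  The two give
  different logistic coefficients; users comparing against the packaged
  arc-criterion coefficients should keep the default.
* The mixed logistic (per-subject random intercept) is fit by the
  variational Bayes approximation in statsmodels.  Its fixed-effect
  posterior standard deviations are noticeably underdispersed, so any
  check phrased in standard-error units should use the plain
  maximum-likelihood logistic (`method="fixed"`), whose SEs are
  well-calibrated; point estimates of the two methods agree closely at
  the trial counts involved.  Perfect separation raises a dedicated
  error.

## Utility models (`utility`)

* Three forms: net reward rate `[αP − ė_r·t_r − e_m]/(t_r + t_m)`; no time
  cost `αP − ė_r·t_r − e_m`; reward-only discounting
  `αP/(t_r + t_m) − ė_r·t_r − e_m`.  α carries joule-equivalent units
  because it is differenced with metabolic cost.
* Duration optimisation: coarse grid over (0.2, 2.0) s followed by bounded
  scalar refinement; the grid guards against flat or multimodal utilities
  at extreme rewards, and agreement with a dense grid oracle within
  1e-3 s is tested on random contexts.  A maximum at a bound triggers a
  warning (it indicates a degenerate parameterisation, e.g. zero reward
  with zero reaction time).
* α fitting: scalar least squares against observed condition-mean
  durations, coarse scan then bounded refinement over [−500, 500] with
  expansion on demand.  The bracket admits negative rewards because the
  reward-only-discounting form genuinely fits best at α < 0; restricting
  to positive rewards would pin that model's fit to the bracket edge.
* The arc-target predictions reuse the circular-target α verbatim — no
  parameter touches the arc-target observed durations.
* **Point estimates vs bootstrap means.**  The packaged reference values
  for predicted durations are bootstrap means; maximising with point
  parameters lands within ~0.2 % of them for the metabolic optima and
  within ~0.5 % for the net-reward-rate predictions.  Comparisons are made
  at 2 % for the utility chain.
* **Model-comparison caveat.**  Fit to the circular-target means, the
  net-reward-rate form transfers best to the arc-target conditions, and
  the no-time-cost form transfers poorly — both as expected.  The
  reward-only-discounting form, however, fits the circular-target means at
  a negative α and then predicts *faster* arc-target movements, giving a
  transfer error worse than the no-time-cost form under the packaged
  coefficients.  Its reported intermediate ranking is not reproducible
  from the literal model with the packaged group-level constants (no
  parsing of the utility we tried yields it together with a negative
  fitted reward), and the corresponding check in the acceptance suite is
  left failing rather than redefining the model to match.

## Synthetic data (`synthetic`)

The generator emulates the statistical structure the pipeline estimates —
not the biomechanics of real movement.

* **Subjects** draw resting rate from N(73.33, 10.2²) W (cohort sd
  back-computed from the reported standard error over 8 subjects),
  multiplicative lognormal jitter on the metabolic coefficients (σ = 0.05
  on a, 0.10 on b), a logit-scale accuracy-intercept deviation (sd 0.3),
  a reaction-time intercept N(0.164, 0.015²) s with mass slope
  N(5.61e-3, 1e-3²) s/kg, and a per-subject effective-mass offset
  (sd 0.2 kg).
* **Reaction time** is intercept + slope·effective mass + trial noise
  (sd 20 ms), matching the reported linear mass dependence of self-paced
  reaction times.
* **Durations.**  Self-paced durations are lognormal around the packaged
  condition means (within-subject CV 10 %, between-subject scale σ = 0.08,
  consistent with the reported between-subject confidence intervals).
  Prescribed-speed blocks realise durations near the timing window plus a
  0.25 s overhead: the task times feedback at first target entry while the
  analysed duration runs from onset to full stop, and the fitted power law
  matches the reported gross-power range (≈ 93–172 W without load) only on
  this realised scale — at a literal 0.25 s duration it would imply
  kilowatt rates.
* **Endpoints.**  Endpoint scatter is isotropic Gaussian around the aim
  point with the sd calibrated per trial so that the success probability
  under the experiment's target geometry equals the configured logistic at
  that trial's (t_m, m): closed-form Rayleigh inversion for circular
  targets, 1-D root finding on the radial×tangential success integral for
  the arc.  Certain success maps to zero scatter.  This reproduces the
  logistic exactly by construction; it does not claim that real endpoint
  noise is isotropic or Gaussian.
* **Gas exchange.**  Block power is composed by time-weighting the target
  moving rate and resting rate (the inverse of the moving-time
  normalisation), perturbed so the recovered moving rate has sd 25 W —
  the residual scale of the reported metabolic fit — plus AR(1) wiggle in
  the trace and an optional first-two-minutes exponential on-transient
  that the steady-state window must exclude.  Flows split the power at a
  fixed respiratory exchange ratio of 0.85 (only the Brockway combination
  matters downstream).
* What passing these tests shows: the pipeline recovers, at the study's
  scale and noise level, every parameter the generator plants (metabolic
  coefficients, logistic betas, reward, reaction-time slope), and its
  bootstrap intervals attain near-nominal coverage.  What it does not
  show: robustness to model misspecification (non-logistic accuracy,
  non-power-law energetics, anisotropic endpoint noise, non-steady-state
  metabolism), which real data may exhibit.

## Problem sizes in the test suite

The suite runs the metabolic cohort at its native size (8 subjects,
24 blocks); recovery checks average over 5–10 generator seeds; the
bootstrap-coverage study uses 200 outer replications with 200 bootstrap
replicates each; oracle-equivalence checks use 100 random configurations.
The full suite completes in a few minutes on one CPU.

## Known limitations

* The arm model is planar with no gravity torques or muscle dynamics; the
  evaluation posture along the reach is a modelling choice the source
  protocol leaves open.
* The movement-segmentation offset rule approximates an algorithm whose
  reference implementation is not published; only its threshold constants
  are.
* Out-and-back (quadrant-target) trials are generated and processed but
  not modelled by the utility chain (their movement structure differs
  from the out-and-stop paradigm).
* The reward α is identified only jointly with the packaged metabolic and
  accuracy coefficients; it is not an interpretable currency on its own.
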