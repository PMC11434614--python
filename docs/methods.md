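# Methods

## Model

`reachseq` simulates sequences of planar reaching movements under
finite-horizon linear-quadratic-Gaussian (LQG) control. The effector is a
point mass (the standard reduced model of the arm moving a robotic handle)
driven by low-pass-filtered motor commands:

    m ẍ = −g ẋ + f_x + f_load        m ÿ = −g ẏ + f_y
    τ ḟ_x = u_x − f_x                τ ḟ_y = u_y − f_y

with state z = (x, y, ẋ, ẏ, f_x, f_y). Defaults: m = 2.5 kg, viscous
constant g = 0.1 N·s/m, muscle time constant τ = 0.1 s. The system is
discretized by explicit first-order Euler, A_d = I + δt·A and B_d = δt·B with
δt = 10 ms. This is deliberate: the model is *defined* by the Euler update
(the controller and all downstream quantities are exact consequences of it),
not an approximation of a matrix exponential, and the package tests the
identities A_d − I − δt·A = 0 and B_d − δt·B = 0 directly. Additive motor
noise ε ~ N(0, σ·B_d·B_dᵀ) with σ = 0.2 enters through the command channels;
we build the covariance from the *discrete* B_d because the noise term lives
in the discrete-time update.

The state is augmented with the planar coordinates of every sequence target.
Target rows evolve as constants (identity dynamics, no control, no noise), so
a single time-varying linear feedback law u_t = K_t ẑ_t addresses the whole
sequence, and the columns of K_t over target coordinates are per-target gains:

    u(t) = k1(t)·T1 + k2(t)·T2 + … + kx(t)·x̂_body(t)

exactly (an exact column partition, tested to machine precision). The
overlap in time between k1 and k2 is the model's operational definition of
coarticulation: a two-reach sequence is "chunked" to the extent that the
second target's gain is non-zero while the first reach is still in flight.

## Task costs

Two quadratic cost families encode a k-target sequence over N steps with
element ends N1 < … < Nk = N:

* **terminal** — position error w.r.t. target i (weight w1 = 500) and squared
  velocity (per-target dwell weight) charged only at N_i; motor cost
  w4·‖u‖² = 10⁻⁴·‖u‖² at every step.
* **buildup** — the same penalties accrue throughout each element, scaled by
  ((t − N_{i−1})/(N_i − N_{i−1}))^b with b = 20 for the first element and 4
  for later ones, concentrating cost near each element's end while softly
  penalizing the whole path.

The dwell weight at the intermediate target is the experimental manipulation:
w2 = 0.1 models the rapid-transfer (GO) instruction and w2 = 1 the stop-over
(STOP) instruction. The dwell weight at the final target has no canonical value;
we default it to w3 = 1 because both tasks require holding at the final
target. In the buildup family the second element's
velocity term is the one genuinely open choice; we implement it symmetrically to the second element's position term, with
weight w3 and exponent b2, paralleling the terminal family.

Element durations are likewise free parameters; we use N1 = 0.6 s and
N2 = 1.2 s, consistent with the 500–650 ms reach window enforced in the
experiments, and end the simulation at N2 (costs end there, so a
post-sequence hold would be pure drift under zero terminal gains).

Gains come from the standard backward Riccati recursion (no state-control
cross terms). With additive Gaussian noise the optimal gains are unchanged
(certainty equivalence) — the recursion never sees σ, and a test asserts
bit-identical gains for σ = 0 and σ = 0.2. The recursion is verified against
an independent brute-force dynamic program (grid search over discretized
controls with iterative refinement) on scalar and two-dimensional toys, and
by the property that 100 random perturbations of the gain sequence never
lower the noiseless closed-loop cost.

## State estimation with sensory delay

Sensory feedback reports the body state Δ = 50 ms (5 steps) late. We use the
standard device for fixed-delay LQG: stack the last d body-state copies under
the current augmented state (dimension 6(d+1) + target rows), let the
observation read the oldest copy plus white noise (σ_ω = 10⁻⁴ per channel),
and run a Kalman filter on the stacked system; the head block is the estimate
of the present state. Targets are displayed to the subject, so their rows
carry zero prior and process covariance and are never corrected — they stay
exact, which also avoids a singular innovation covariance from "observing"
deterministic rows.

External loads are deliberately absent from the filter's internal model: an
unexpected push is discovered only through innovations, so its influence on
the estimate cannot precede onset + Δ (tested exactly in the noiseless case).
We keep the load out of the estimator, matching the unpredictable-perturbation
logic of the emulated experiments. Estimating the load as an
augmented state is a possible extension, not implemented.

The filter is initialized at the true state (trials start from a stabilized
hold) with a small diagonal prior (10⁻⁶) on body rows. The covariance
recursion is data-independent, so the gain sequence is precomputed once per
task and shared across trials; a test confirms the stepwise filter and the
precomputed path agree with a batch least-squares (joint-Gaussian
conditioning) oracle.

## Trials and perturbations

A trial is a closed-loop rollout from rest at the home position: T1 is 18 cm
ahead on the midline, T2 is displaced ±8 cm laterally from T1. Perturbations
are lateral force pulses of ±7 N released when the *true* forward position
(the robot knows the hand position, the participant's estimator does not)
crosses ¼ of the forward distance (4.5 cm): 10 ms linear rise, 200 ms total
nonzero width including the rise (a config switch `width_includes_rise`
selects the alternative reading), and a symmetric 10 ms ramp-down appended
after the plateau to avoid a force discontinuity. Noiseless rollouts are
bit-identical across runs; left/right target reflections (with the load sign
flipped) produce exact x-mirrors.

The three-reach extension reuses the same machinery on a 12-dimensional
augmented state. There is no canonical three-target geometry, so we
place T3 8 cm above or below T2; the qualitative results (distinct velocity
profiles for the two final-target placements, dwell-weight-dependent
first-reach curvature) do not depend on this choice.

## Analysis pipeline

* **Lateral deviation** — mean signed perpendicular distance (m) of the first
  reach from the home→T1 line, positive rightward. The first-reach segment
  runs from movement onset (speed > 2 cm/s; movement onset has no
  single standard definition, so this threshold is a fixed documented choice) to the first
  entry into the T1 proximity zone, falling back to N1 if the zone is never
  entered; a `segment="n1"` rule is available for perturbed trials with
  longer paths.
* **Dwell velocity** — minimum root-mean-square planar speed within 0.5 cm of
  the T1 edge. The T1 radius defaults to the same
  0.6 cm as the home target, configurable.
* **Muscle proxy** — rectified lateral command components (positive parts of
  ±u_x), smoothed with a 30 ms moving average, standing in for a
  pectoral/deltoid-like agonist–antagonist pair that produces lateral force.
  This is an explicit modeling proxy and is labeled as such in outputs.
* **Delta response** — traces aligned to perturbation onset (unperturbed
  trials to the matched pseudo-onset, i.e. the trigger-crossing step), the
  block-matched unperturbed mean subtracted, and means taken over the
  classical reflex epochs (baseline −100–0, R0 0–20, R1 20–45, R2 45–75,
  R3 75–105, voluntary 120–180 ms).
* **Contrasts** — paired t-tests across participants, reported unadjusted
  across epochs (epoch samples enter one comparison each and neighbouring
  samples are not independent); Holm–Bonferroni adjustment is provided for
  the first/last-trial block analysis where a family of comparisons is made.

## Synthetic cohorts

`generate_cohort` reproduces the experimental bookkeeping per participant:
9 sets × 10 blocks (5 left / 5 right second target, shuffled within set) ×
10 trials (8 unperturbed + one rightward + one leftward load at random
positions) = 900 trials, 20% perturbed. Between-participant variability is a
±5% uniform jitter on w1, w2 and the motor-noise scale — enough spread for
paired statistics without changing the qualitative structure. All randomness
derives from one seed; the manifest records the design, jitter draws and
parameters for exact regeneration. The generator emulates trial structure and
motor/sensory noise only: no trial failures, timing windows, scores,
electromechanical EMG artifacts, learning or fatigue. Passing round-trip
tests therefore shows that the analysis code recovers what the model puts in,
not that the model captures every feature of human data.

## Which cost family is used where

The terminal family is the primary model of unperturbed sequence execution
and is used for the headline transfer-speed check. For the
perturbation-response analyses (gain-onset ordering and the
deviation-contrast shrink between GO and STOP) the package uses the buildup
family, the variant of the two that tracks human perturbation behavior most
closely. This is not an arbitrary preference; under terminal costs
two structural facts blunt those particular measures:

* The GO and STOP objectives differ only in the dwell weight at N1, which
  enters the backward recursion only for t < N1 — the gain schedules are
  *identical* for t ≥ N1. With terminal costs k2 stays below 10% of its peak
  throughout the first reach in both tasks (GO ≈ 2%, STOP ≈ 1% of peak early
  on), so the 10%-of-peak onset falls just after N1 in both and cannot order
  them, even though the STOP k2 is uniformly smaller before N1 (a fact the
  suite asserts directly). Under buildup costs the crossing happens before
  N1 and orders strictly (GO step 52 < STOP step 53).
* The terminal-cost deviation contrast between loads toward vs away from T2
  is positive in GO for both signs but shrinks only ~2× in STOP; the buildup
  model shrinks it ≥3×.

## Known limitations

The perturbation response of the *control signal*, δu(t) = u_perturbed −
u_unperturbed, is exactly independent of target locations in this model:
the policy is linear, targets are constant state rows shared by both trials,
and superposition cancels them in the difference. Sequence-direction
dependence of the rectified muscle proxy therefore arises solely from
rectification against the direction-dependent baseline drive, and its
long-latency (R2/R3) epoch means contrast by direction almost equally in GO
and STOP (only the voluntary epoch dissociates, ≈2×, because the baseline
drives diverge near N1). A genuinely gain-mediated, task-gated long-latency
modulation — as observed in human EMG — would require a policy that is
nonlinear in the state or gain schedules that depend on target values, both
outside this model class. The cohort round-trip test asserts the epoch
dissociation anyway and fails there by design, documenting the boundary of
the model rather than hiding it.

Other non-goals: nonlinear limb biomechanics, gravity, signal-dependent
(multiplicative) motor noise, reaction-time modeling, trial scoring logic,
adaptation or learning across trials, and infinite-horizon control.

## Problem sizes and numerics

Default simulations run 120 steps on a 10-dimensional augmented state with a
40-dimensional stacked filter; a full five-participant cohort (900 trials per
participant and task) generates in well under a minute. The Riccati pass
symmetrizes the cost-to-go each step and raises a named error on non-finite
values; the filter uses the Joseph-form covariance update and a pseudoinverse
for the (degenerate, fully deterministic) zero-covariance innovation case.
Dwell velocity returns NaN with a `zone_not_entered` reason code when the
hand never reaches the T1 zone; gain onset returns `None` ("never") for an
all-zero series; zero-variance paired contrasts return defined sentinels
((0, 1) for all-zero differences, signed infinity with p ∈ {0, 1} for
constant non-zero differences).
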