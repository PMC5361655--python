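# Methods

## Scope and model

`reflexwalk` implements a sagittal-plane neuromechanical model of human
walking controlled by delayed spinal reflexes, together with the five
classic gait-disturbance protocols used to probe spinal control
(afferent-pulse stimulation, tendon tap, imposed ankle stretch, trip,
slip) and the statistics with which model responses are compared to
human EMG response trends.  The model belongs to the reflex-control
family of neuromuscular walking models (seven rigid segments, Hill-type
muscle–tendon actuators, phase-gated proprioceptive feedback); constants
not fixed by the package's own contracts follow that family's published
magnitudes, with the concrete values below.

## Rigid-body mechanics

Seven segments — head-arms-trunk (HAT), and thigh, shank, foot per leg —
move in the sagittal plane with nine generalized coordinates: hip-point
position (x, y), trunk lean, and hip/knee/ankle angles per leg (hip
flexion, knee flexion, ankle dorsiflexion positive).  Segment lengths
scale linearly with body height and masses with body mass using standard
anthropometric regression fractions (HAT 0.678 of mass, thigh 0.100,
shank 0.0465, foot 0.0145; lengths 0.470/0.245/0.246/0.152 of height;
radii of gyration 0.496/0.323/0.302/0.475 of segment length).  The
equations of motion are assembled per step from per-segment
center-of-mass Jacobians, M = Σ m JᵀJ + I wᵀw, with velocity-product and
gravity terms on the right-hand side, and solved directly (9×9).  The
assembly is verified against an independent sympy Lagrangian derivation
(agreement ~1e-14) and by ballistic energy conservation (<0.1% drift per
second at the default step).

Integration is symplectic (semi-implicit) Euler at a fixed step of
0.5 ms (configurable 0.1–0.5 ms).  A fixed step keeps delay buffering
exact and trajectories bit-reproducible; the energy test quantifies the
price.  Falls are detected as hip height below 0.7 of standing hip
height, trunk lean beyond 1.2 rad, or any non-finite coordinate.

Ground contact uses two points per foot (heel 30% of foot length behind
the ankle, ball 70% ahead; ankle 26% of foot length above the sole).
Normal force is a damped spring F = k·p·(1 + c·ṗ), clipped non-negative
(k = 120 kN/m at 80 kg, c = 1 s/m); friction is anchor-based stiction
(tangential spring–damper to a contact anchor advected with the
belt/ground surface velocity) clipped to a Coulomb cone (μ = 0.9), which
supports split-belt speed changes natively.

## Muscle–tendon units

Nine muscle groups per leg (HFL, GLU, HAM, RF, VAS, BFSH, GAS, SOL, TA)
are Hill-type: contractile element (CE) with bell-shaped force–length
(width w = 0.56, residual 0.05 at the edges) and Hill force–velocity
(curvature K = 5, eccentric plateau N = 1.5), in series with a quadratic
tendon (strain 4% at F_max), with parallel elasticity beyond l_opt and a
compression buffer below (1−w)·l_opt.  CE velocity is obtained each step
by inverting the force–velocity relation from the tendon/parallel force
balance.  Activation follows first-order excitation–activation dynamics
(τ = 10 ms); stimulations are clamped to [0.01, 1].

MTU length changes with joint angle through constant moment arms at the
hip and cosine-varying arms r(φ) = r₀·cos(φ − φ_max) at knee and ankle;
the CE-side excursion is attenuated by a pennation factor ρ while the
torque-producing arm is the full geometric r(φ), as in this model
family.  `mtu_kinematics` reports d(l)/d(φ) (the CE-side signed arm),
which the tests check against finite differences.  Key constants
(1.80 m / 80 kg template): F_max 2000/1500/3000/1200/6000/350/1500/4000/
800 N, l_opt 11/11/10/8/8/12/5/4/6 cm, v_max 12 l_opt/s (SOL 6), r₀ at
hip 10/10/8/8 cm, knee 6/5/4/5 cm, ankle 5/5/4 cm.  Muscle mass for the
metabolic model is F_max·l_opt·ρ_dens/σ with density 1059.7 kg/m³ and
specific tension 0.25 MPa.

## Spinal reflex controller

Afferents are normalized muscle force (F/F_max), CE length (l/l_opt) and
CE velocity (v/v_max, shortening positive), plus trunk lean (and rate)
and per-leg load (normal force / body weight).  Each signal is read
through a ring buffer at its transport delay: 20 ms for ankle muscles,
10 ms for knee/thigh and the load afferent, 5 ms for hip/trunk.

Stance law (per leg): positive force feedback to SOL, GAS and VAS; TA
stretch reflex inhibited by SOL force; VAS inhibition near knee
extension (via the delayed VAS-length/velocity proxy) and during
contralateral loading; trunk-balance PD (gains k_p, k_d around a lean
reference θ_ref) driving GLU/HAM (forward lean) and HFL (backward lean),
scaled by the leg's load share; a double-support modulation that boosts
HFL and suppresses GLU/VAS on the *trailing* leg only, initiating swing.
Swing law: HFL stretch reflex with a lean-proportional bias, opposed by
HAM stretch; HAM force feedback (and a GLU pathway driven by HAM force)
braking the leg late in swing; the TA stretch reflex holding the foot;
a BFSH stretch reflex flexing the knee; late-swing VAS/GAS pathways that
stay silent in undisturbed gait (their gains are free).  The stance SOL
pathway carries no velocity-afferent term — structurally pure force
feedback — which grounds the velocity-feedback attribution analysis.

Stance/swing gating follows foot loading (threshold 3% of body weight):
loading switches the gate immediately, unloading only after persisting
30 ms (so brief disturbance-induced unloading does not silence the
stance reflexes), and the two laws cross-fade over 10 ms.  Heel-strike
and toe-off events are timestamped at the switching step.

## Gait optimization

The 32 reflex parameters are tuned per target speed by a
covariance-matrix-adaptation evolution strategy (implemented in-package,
(μ/μ_w, λ) with rank-one and rank-μ updates, box-normalized parameters,
default λ = 14) minimizing

    J = C_E + c_v · |v_avg − v_tgt|,   c_v = 100,

where C_E is the metabolic energy the muscles consume over the scored
window, expressed per unit body mass and distance (cost of transport,
J/(kg·m)); in these units c_v = 100 makes a 0.05 m/s speed error
comparable to the entire energy term, so the target speed binds.  The
metabolic rate is activation/maintenance heat (128 W per kg of active
muscle mass, scaled by activation) plus shortening heat (25% of positive
CE power) plus positive CE work; it is zero for a massless/quiescent
muscle set and additive over muscles and time.  Each evaluation
simulates 35 s from a standing start at the target speed (5 s transient
discarded, 30 s scored, ≥ 20 strides).  A fall (including numerical
divergence) costs 200 − 2·min(distance, 50), which strictly rewards
partial progress and dominates every non-fall cost.

Walking limit cycles here are chaotic: truncating a parameter file to 10
significant digits changed trajectories enough to fall within seconds.
Fixture parameter sets are therefore written with 17 digits and accepted
only if the file as written reproduces a 60 s walk at the target speed.
The shipped fixtures (one per target speed: 0.83, 0.97, 1.11, 1.20 m/s)
were obtained by chained warm-started runs of a few thousand evaluations
each; they are versioned so all downstream analyses run in minutes.

## Disturbance protocols

Every trial restarts from a stored limit-cycle snapshot (full mechanical
and neural state including delay buffers, taken at a heel strike of the
target leg after a 12 s settle), so trials never accumulate state, and
each disturbed trial is paired with a bit-identical undisturbed control.

* Afferent pulses (electrical-stimulation analogue): 10 ms square pulses
  of normalized amplitude 1.0 (F_max / l_opt / |v_max| units) added to
  all three afferents of every muscle at record time; 16 stride-phase
  conditions.
* Tendon tap: imposed MTU stretch Δl = min(E_kin/F(t₀), 0.05·l_opt)
  with E_kin = ½mv² of the hammer (90 g, 1.5 m/s → 0.10125 J), applied
  as a 5 ms triangular ramp; 16 stride phases; taps on a slack muscle
  are capped and flagged.
* Ankle stretch: dorsiflexion ramp of 8° at 250°/s (32 ms) imposed by
  prescribing the ankle coordinate exactly (constrained solve, i.e. an
  idealized stiff servo), held 100 ms, then released; 8 stride phases.
* Trip: a 2.2 kg block (0.1 × 0.1 m, contact stiffness 20 kN/m, ground
  friction 0.8) placed from the undisturbed reference trajectory so the
  swing foot's ball strikes its front face at the requested swing
  fraction (5–75%); the block translates with Coulomb ground friction
  (no rotation — a documented simplification).  Conditions whose foot
  path clears the block are reported unrealizable and excluded.
* Slip: the stance-side ground/belt surface velocity ramps by delta_v
  (0.1–0.5 m/s) over 50 ms, starting exactly 150 ms after the detected
  heel strike; the default sign moves the surface backward (belt
  speed-up), configurable.

Zero-magnitude disturbances of all five protocols are bit-exact no-ops,
which the tests assert.

## Response statistics

The scalar response of a muscle is the signed peak of the activation
difference (disturbed − undisturbed) inside a protocol-specific window
shifted by the muscle's transport delay (pulse/tap 0–40 ms, stretch
10–60 ms, trip 20–100 ms, slip 20–150 ms after onset); a window-mean
mode is available.  Reference bands are peak-normalized (max |mean| = 1,
s.d. scaled by the same factor).  Trend similarity scales a model trend
by one non-negative factor k to maximize the count of conditions within
±1 s.d. of the reference mean; the maximization is exact over the
per-condition interval endpoints [mean ± s.d.]/model, with ties broken
by least squares to the mean, and is verified against a dense-grid
maximizer on 1000 random instances.  A multiplicative-only scaling is
the default because responses are baseline-subtracted changes (zero must
map to zero); an additive offset is available behind a flag for
sensitivity analysis.  Amplitude ratios (joint-level and whole-body
protocols only) compare peak responses after normalizing each trend by
its own peak background activation.

Evoked spike duration is measured as the contiguous interval around the
peak activation excess during which the excess exceeds 20% of peak — a
standard burst-duration measure that excludes later mechanically
mediated after-responses.

The velocity-feedback attribution replicates the correlation analysis of
ankle-perturbation studies: constant-velocity dorsiflexion ramps at one
mid-stance phase, with rates spanning the physiological range of stance
dorsiflexion velocities (31.25–125°/s) and a duration (80 ms) that keeps
the imposed velocity constant across the whole short-latency response
window, so the regressor is unambiguous.  The achieved ankle
angular-velocity change (imposed minus undisturbed) is regressed against
the SOL response amplitude; the fitted slope is applied to the positive
(dorsiflexion) part of the undisturbed stance ankle-velocity profile;
and the attributed activation is expressed as a percentage of mean total
SOL stance activation.  Because imposed stretch velocity and muscle
force co-vary, this attribution is strictly positive even though the
model's SOL stance pathway contains zero velocity gain — the confound
the analysis is designed to expose.  The size of the attribution is
bounded by the muscle's stretch-response amplitude, which the eccentric
force–velocity plateau and the series tendon compliance self-limit: the
force transient a stretch can evoke saturates near 1.5·a·F_max·f_l, so
the attributed share scales with the ratio of stretch-evoked to
background force rather than with the reflex gain.

## Synthetic reference data

The generator emulates the *structure* of human reference data — smooth
peak-normalized response trends over 5–16 conditions with ±1 s.d. bands —
not their physiology: trends are Gaussian-bump mixtures on a normalized
condition axis; the band mean is k*·latent with k* recoverable by
construction; a requested number of conditions can be made unreachable
for any non-negative scale (mean flipped across zero by more than one
s.d.), giving fixtures with a known best overlap (e.g. exactly 12/16 =
75%); in-band noise perturbs the latent trend by less than the local
s.d.  EMG-like trials are smooth envelopes plus band-limited (0–15 Hz)
noise with an injected Gaussian response bump of known height; disturbed
and control traces are independent realizations, as in real experiments.
Passing tests on these fixtures validates the statistics and pipeline
mechanics; they say nothing about physiological realism of real EMG.

## Problem sizes and known limitations

Tests and the acceptance script use one snapshot per speed, single
trials per condition (the model is deterministic), 30–35 s walking
checks, and 1000-instance statistical cross-checks; these sizes were
chosen so the full suite runs in minutes on one core.  Known
limitations: sagittal plane only (no lateral balance); both hips share
one point; the trip block does not rotate; tendon-tap and
electrical-stimulation electrophysiology is abstracted into mechanical/
afferent equivalents; the human-vs-model overlap percentages of the
source experiments require digitized human EMG, which is an optional
input here, not shipped data; and optimized gaits, while stable for
60+ s, are chaotic limit cycles whose fine structure depends on the full
precision of the parameter files.
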