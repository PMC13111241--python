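# Methods

## Problem and model

`gaitphys` estimates neuromuscular fatigue (five ordinal levels, L0 baseline
to L4 severe) from distributed wearable inertial sensors during gait, jointly
with continuous bilateral-asymmetry indices. The core idea is
physics-informed learning: a hierarchical attention network predicts not only
the fatigue class but also intermediate physical quantities — joint-angle
trajectories θ ∈ ℝ^{T×6}, ground reaction force (GRF), centre-of-mass (COM)
velocity and mechanical energy — and four differentiable biomechanical
constraint losses regularize those quantities toward physical plausibility:

1. **Kinematic** — interval hinge on anatomical joint ranges (hip
   flexion–extension ±35°, knee flexion 0–80°, ankle ±30°, optional hip
   abduction ±15°) plus a κ-weighted (κ = 0.1) squared second-difference
   smoothness penalty.
2. **Dynamic** — ‖F̂_g − F_g^meas‖² + κ₁‖ΣF − m a_c‖² + κ₂‖Στ_e − I α‖²
   (κ₁ = 0.5, κ₂ = 0.3), where a_c comes from the differentiable chain
   θ → segment positions (forward kinematics) → mass-weighted COM →
   central-difference acceleration.
3. **Symmetry** — squared normalized bilateral difference of left/right
   trajectories after a half-cycle shift (50 samples on the 101-point grid),
   with weights w_k⁰·exp(−β·y_f), β = 0.15, relaxing the constraint as
   fatigue rises.
4. **Energy** — per-cycle work balance |E(t_f) + W_d − E(t_i)|², with
   dissipated work W_d = c·∫‖F_g‖dt (trapezoid rule) and c a learnable
   scalar initialized at 0.05.

Constraint weights follow a curriculum λ_i(e, y_f) = λ_i⁰·α(e)·β(y_f) with
base weights (0.1, 0.15, 0.08, 0.12), a warmup floor α = 0.1 for the first
E_w epochs, a linear ramp to 1.0 over E_r epochs, and fatigue scaling
β = 1 + 0.15·y_f. E_w = 20 and E_r = 80 by default (configurable): the ramp
completes well before a standard 200-epoch budget. At inference the scaling
uses the arg-max predicted level, recomputed per batch.

The total objective is L = L_c + L_r + L_u + Σλ_i L_p^(i) + η‖θ‖², with
cross-entropy classification, MSE asymmetry regression, a heteroscedastic
Gaussian negative log-likelihood (a log-variance head provides the
training-time σ; Monte-Carlo dropout adds epistemic spread at inference),
and decoupled L2 (η = 10⁻⁵) via AdamW.

## Differentiation substrate

All constraint losses, the rigid-body layer and the network are built on a
compact reverse-mode automatic-differentiation engine over numpy
(`gaitphys.autodiff`): a dynamic tape with broadcasting-aware primitives
(arithmetic, matmul, trig, reductions, slicing, padding, softmax, layer
norm, dilated causal convolution) and an AdamW optimizer with global-norm
gradient clipping and cosine annealing. Gradients of every primitive are
unit-tested against central finite differences; the full chain
θ → p_s → p_c → a_c is verified the same way. The engine defaults to
float64 for verification; training switches to float32, which roughly
halves step time at these model sizes.

## Rigid-body layer

A sagittal-plane seven-segment model (pelvis–trunk, bilateral thigh, shank,
foot; x forward, y up, rotations CCW about the mediolateral axis; 1 DOF per
joint, matching the 6-dimensional θ). Anthropometrics come from the standard
Winter body-segment proportion table (shipped as a versioned CSV): segment
lengths as fractions of stature, masses as fractions of body mass (the
pelvis–trunk segment absorbs the residual so Σm_s = m exactly), COM offsets
and gyration radii per segment, I_s = m_s(r_s L_s)². The foot is a short
distal segment; the GRF acts at a fixed centre-of-pressure fraction (0.5) of
foot length.

Inverse dynamics is a planar recursive Newton–Euler pass from the feet
upward, using closed-form segment COM accelerations (chain-rule derivatives
of the trigonometric forward kinematics, not grid differences), so it agrees
with an independent sympy-derived Lagrangian oracle for the 3-link leg with
external COP force to ~1e-15 relative. The torque sign convention is CCW
torque applied by the proximal segment on the distal one.

Mechanical energy uses the COM decomposition E = ½m‖v_c‖² + ½ΣI_s ω_s² +
m g h_c. This is exact for a single rigid body (König) and an approximation
for articulated motion, since it omits the kinetic energy of segment motion
relative to the COM; the energy constraint therefore regularizes a
consistent, slightly smoothed energy measure rather than the full multibody
energy. The rotational Newton–Euler term is likewise an interpretation: the
whole-body inertia about the COM is approximated by a standing-posture
constant, α by the mass-weighted mean segment angular acceleration, and
Στ_e by the GRF moment about the COM.

Time derivatives elsewhere (θ̇, θ̈, v_c, a_c) use central differences on the
interior with one-sided first-order boundaries — exact for polynomials up to
degree 2 and a fixed-coefficient linear operator, hence transparent to
autodiff.

## Pre-processing and segmentation

* Zero-phase low-pass: order-4 Butterworth at 20 Hz applied
  forward–backward (`sosfiltfilt`), i.e. the squared magnitude response.
* Orientation: complementary filter q̂(t) = normalize(α·[gyro update] +
  (1−α)·q_am) with α = 0.98. The gyro term uses a proper quaternion
  increment q̂ ⊗ [1, ωΔt/2] rather than the dimensionally informal additive
  form, and q_am is a TRIAD-style attitude (tilt from gravity, heading from
  the horizontal magnetometer projection). Zero-norm accelerometer samples
  fall back to gyro-only updates; the estimate is renormalized every step.
* Outliers: modified Z-score 0.6745·(x − median)/MAD (Iglewicz–Hoaglin) at
  |Z| > 3.5; flagged runs of ≤ 4 consecutive samples are replaced by a cubic
  spline through unflagged neighbours, longer runs stay flagged unrepaired.
  MAD = 0 (constant signal) disables flagging.
* z-scoring uses training-split statistics persisted with the checkpoint.
* Contact events: vertical-GRF upward crossing of 20 N (initial contact,
  IC) and downward crossing of 30 N (terminal contact), with alternating
  IC/TC hysteresis and a 50 ms debounce. The kinematic backup marks IC at
  the first zero crossing after the mid-swing positive peak of the shank
  sagittal angular velocity. With this package's CCW-positive axis that
  crossing is positive-to-negative; the convention was fixed by validating
  against force-based events on noiseless synthetic recordings (agreement
  ≤ 2 samples).
* A gait cycle is [IC_i, IC_{i+1}) of the same foot, segmented per foot;
  each cycle is cubic-spline resampled to the canonical 101-point 0–100%
  grid. Quality control drops cycles with duration outside [0.4, 1.2] s,
  peak vertical force below 80% body weight (body weight = m·9.81 N), or
  non-monotonic timestamps.

## Feature extractor

A frozen manifest of exactly 127 descriptors in five domains:
spatiotemporal (11), kinematic (33), kinetic (10), symmetry (48 = 16
bilateral base features × {ratio r, difference d, normalized index s}),
frequency (25 = 5 designated channels × {dominant frequency, normalized
spectral entropy, three band-power fractions for 0–3 / 3–8 / 8–20 Hz}).
The count is enforced structurally: unavailable inputs (e.g. missing GRF)
produce NaN plus a missing mask, never a shorter vector. Conventions chosen
where the descriptor lists leave room: loading rate is the maximum mean
slope of vertical force over a sliding 20 ms window in early stance;
braking/propulsive impulses integrate the negative/positive
anterior–posterior GRF; vertical COM displacement double-integrates
mean-removed trunk vertical acceleration (per-cycle drift correction);
spectral entropy uses natural logs normalized by log(bins) to [0, 1].
Note that the entropy of a single-realization periodogram of white noise
sits (1 − γ) ≈ 0.42 nats below log(bins); tests compare against that
corrected expectation.

## Network

Sensor fusion embeds each of the 8 sensor streams (9 channels:
accelerometer, gyroscope, magnetometer triaxes) with a shared kernel-3
convolution to d dimensions, adds learnable per-slot position encodings,
applies 8-head self-attention across the sensor axis, then residual + layer
norm + feed-forward, and mean-pools the sensor axis (masked mean under
sensor failure; masked sensors also get −∞ attention logits). The temporal
module runs two parallel pathways on the 101-sample cycle: six residual
dilated causal convolution blocks (kernel 3, dilations 1…32, receptive
field 1 + 2·63 = 127 samples) and a pre-norm transformer; an element-wise
learned sigmoid gate merges them. Heads: θ through a tanh scaled to ±2.5
rad (deliberately super-anatomical so the kinematic hinge stays active),
linear heads for GRF (in body-weight units), COM velocity and auxiliary
energy; classification by temporal mean-pooling + a narrowing MLP
(paper-scale widths 256–128–64, tiny profile 64–32) + softmax; regression
by max-pooling + linear, plus a tanh-bounded log-variance head (±4).
Monte-Carlo dropout (default K = 30 passes) yields predictive mean and
variance; with dropout 0 the variance is exactly 0.

Two profiles ship: the printed full architecture (64-d sensor embeddings,
256-d temporal, 8 heads, 4 transformer layers) and a desk-scale tiny
profile (16/32-d, 4 heads, 1 transformer layer) used by all synthetic
experiments so they run in minutes on one CPU core.

## Training-time choices

Constraint terms are normalized per sample and time step and by natural
physical scales (body weight for force terms, (mg)² for energy residuals)
so the printed base weights act on O(1) quantities. The training-time
symmetry guard widens the denominator threshold to 0.05 rad: randomly
initialized trajectories otherwise produce unbounded normalized ratios and
destabilize early optimization; evaluation semantics (ε = 10⁻⁶) are
unchanged. Biomech and regression heads are initialized near zero so
training starts physics-feasible. The auxiliary energy head is trained by
MSE toward the (detached) chain-computed E(t); the energy constraint itself
always consumes the chain value, so it cannot be satisfied by an
unconstrained head. Desk defaults: 30 epochs, batch 16, AdamW lr 3·10⁻³
with cosine annealing, gradient clipping at norm 1.0, subject-disjoint
validation split. Checkpoints are single-file npz archives with weights,
model config and normalization statistics; exact mid-run resume (optimizer
moments + RNG state) is not persisted.

## Synthetic cohort

The generator emulates the study conditions, not any recorded dataset.
Joint angles are truncated Fourier series (2 harmonics per joint) with
healthy-gait amplitudes inside the anatomical limits at baseline; the right
limb is the left template shifted by half a cycle. Fatigue level l scales
three effects linearly: bilateral DC offsets (0.045/0.055/0.028 rad per
level per unit asymmetry gain for hip/knee/ankle), a right-limb amplitude
deficit (2.5% per level per unit gain), and cadence slowing (1.5% per
level), plus Gaussian cycle-to-cycle amplitude jitter (variability gain ×
level). With the default gains the bilateral ROM symmetry index rises from
≈ 0% (L0) to ≈ 12% (L4). Anthropometrics are drawn from the cohort
statistics (height 172.4 ± 8.1 cm, mass 68.2 ± 11.3 kg). Vertical GRF is a
double-bump curve 1.25·BW·(sin πs + 0.32 sin 3πs) over a 62% stance
(peaks ≈ 1.1 BW, dip ≈ 0.85 BW), anterior–posterior force a braking →
propulsive sine, zero in swing; stride durations are clipped to
[0.42, 1.18] s so ±1-sample detection jitter cannot push a default cycle
over the duration rule. Sensors are synthesized from forward kinematics
with a 1.5 cm double-oscillation pelvis vertical excursion: accelerometer =
R^T(a − g), gyroscope = segment angular rate, magnetometer = rotated unit
north field; noise is additive Gaussian per channel class
(0.05 m/s², 0.01 rad/s, 0.005 a.u., 2 N) or calibrated per channel to a
requested SNR against that channel's AC power. Everything is bit-reproducible
under a fixed seed.

What the generator does **not** emulate: 3-D (frontal/transverse) motion,
soft-tissue artifacts, magnetic disturbances, treadmill-belt dynamics,
double-support force sharing, or inter-subject differences in gait *shape*
(subjects differ in anthropometrics, cadence and noise realization, not in
template). Passing tests therefore demonstrate internal correctness and
end-to-end learnability under the assumed statistical structure, not field
performance on real gait.

The "easy" cohort used for the smoke-learning experiments doubles the
asymmetry gain and raises amplitude jitter to 3% per level — effect sizes
at the strong end of what fatigue studies report — so that five classes are
separable by a tiny model within ~30 CPU epochs on 5 subjects × 5 levels ×
12 cycles. These sizes are the package's desk-scale defaults; larger
cohorts scale linearly.

## Numerical details and edge cases

* Symmetry-loss denominator guard ε (1e-6 eval / 0.05 train) excludes the
  degenerate samples from the sum and reports nothing for them.
* Zero-denominator symmetry indices in the feature extractor (e.g. aerial
  time in walking, identically 0/0) are flagged missing, never infinite.
* The quality filter is idempotent, and rejection logs record which printed rule
  fired ("duration", "force", "timestamps").
* Max-pooling gradients route to the arg-max (first index on ties).
* Attention masking renormalizes over surviving sensors; a fully-masked row
  cannot occur because scenarios mask at most two of eight sensors.
* The divergence guard aborts a training step whose total loss exceeds 10⁶.
* The backward pass frees its tape by default (the closure graph otherwise
  forms reference cycles that defer reclamation of large activations).

## Known limitations

Sagittal-plane kinematics only; quasi-static trunk (the pelvis root is the
world anchor, so trunk-sensor channels carry only the imposed vertical
excursion); the rotational dynamic term and whole-body inertia are
approximations documented above; checkpoint resume restores weights but not
optimizer state; the synthetic cohort's class structure is easier than
real fatigue data, so reported smoke accuracies are upper bounds by design.
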