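# Methods

`synreach` implements a three-stage framework for studying how motor skills
generalize through *spatio-temporal motor synergies* on a simulated
seven-degree-of-freedom arm: (i) acquire reaching skills for limited target
families (reinforcement learning, or a no-training surrogate expert),
(ii) extract a low-dimensional synergy repertoire from each skill's joint
torques with nonnegative matrix factorization, and (iii) reach *new* targets
by linearly combining repertoires and optimizing only their activation
magnitudes with CMA-ES.

## The reaching task

The fingertip starts at a calibrated home position
q_initial = [0.24, 0.0, 0.21] m (shoulder-origin base frame: x forward,
y lateral, z up), must touch a goal q_target at t_target = 0.5 s, and return
home by t_finish = 1 s.  An episode is T = 100 control samples of
Δt = 10 ms.  Goals lie on a radius l = 0.15 m circle around the home
position in one of four planes, parameterized by a direction angle θ:

- horizontal: q_initial + [−l sin θ, −l cos θ, 0]
- sagittal:   q_initial + [−l sin θ, 0, −l cos θ]
- frontal:    q_initial + [0, −l sin θ, −l cos θ]
- upper:      q_initial + [−l sin θ, −l cos θ, z], z = 0.05 m

Training uses the 8-direction horizontal and sagittal sets; the frontal and
upper sets are reserved as genuinely new targets.

The per-sample reward is a pure penalty,

r(t) = −k₂‖a(t)‖²Δt, except at the two checkpoints where position and speed
terms are added: −‖q_target − q(t)‖² − k₁‖q̇(t)‖² at sample 50 and the same
with q_initial at sample 100 (k₁ = 0.002, k₂ = 0.2).  The printed form of
this cost is sign-ambiguous; since every learner here *maximizes* the
return G = Σ r(t), all terms are implemented as negative penalties — the
only reading under which the task is well-posed.  Sample indexing is
1-based: the reward of sample t is evaluated after the t-th control step.

The 18-dimensional observation is [θ (7), θ̇ (7), q_target (3), φ] with
normalized time φ = t/t_finish.  Episodes always start at the calibrated
pose with zero velocity.

## Arm model

The arm has three shoulder joints (flexion/extension, abduction/adduction,
internal rotation), two elbow joints (flexion, forearm pronation) and two
wrist joints (flexion, deviation), with asymmetric human-like joint limits
(e.g. shoulder flexion −1.57..0.70 rad; elbow flexion −1.50..1.05 rad).
Link lengths default to 0.36/0.27 m (shoulder–elbow / elbow–wrist) with two
preset variants, 0.31/0.22 m (shorter) and 0.41/0.32 m (longer); the
wrist-to-fingertip segment is 0.10 m.

Two fixed mounting rotations define the zero configuration: the upper arm
points 0.4 rad forward of vertical and the forearm is orthogonal to it.
Without them the asymmetric limits leave the home position and roughly 10%
of the goal positions outside the reachable workspace; the chosen tilt
centres the limit-bounded workspace on the reaching volume (any tilt in
−0.2..−1.0 rad works; −0.4 is mid-window).

Dynamic parameters are deliberately light: link masses 0.04/0.024/0.01 kg
(slender-rod inertias), rotor armature 0.005 kg m² and viscous damping
0.05 N m s/rad per joint, torque limit ±1 N m (≈150% of the largest static
gravity torque), gravity −9.81 m/s² ẑ.  Two constraints drive this choice:

1. **Reward ordering.**  With k₂ = 0.2 fixed by the task, the summed torque
   penalty of merely holding the arm against gravity must stay well below
   the checkpoint penalty of missing a target (l² ≈ 0.023), or the
   reward-optimal behaviour is a limp arm and no learner will reach.  That
   bounds the gravity-compensation torque to a few tenths of a N m, hence
   the mass scale.  Gravity still matters dynamically: with zero torque the
   fingertip sags ~90 cm of accumulated error over an episode.
2. **Open-loop composability.**  Synergy-decoded torques replay open loop.
   With an undamped chain, a few-percent torque reconstruction error
   integrates into tens of centimetres of drift over one second; viscous
   damping bounds that sensitivity and makes the damping component of the
   torque (d·θ̇) combine almost linearly across target planes.  0.05 was
   chosen once from a scan of 0.02–0.12 as the best balance between
   composability and the extra torque cost damping itself induces.

Armature (0.005 kg m²) regularizes the exact gimbal singularity of the
3-axis shoulder (flexion and internal-rotation axes align at ~90°
abduction), exactly as engine-based models do.

Dynamics are computed by a world-frame recursive Newton–Euler algorithm
(inverse dynamics) and a composite-rigid-body mass matrix; forward dynamics
solves M(θ)θ̈ = τ − c(θ, θ̇) with a dedicated fused numba kernel
(hand-rolled 3-vector arithmetic; the RNEA-column reference implementation
is retained and cross-checked to 1e−13).  Integration is semi-implicit
Euler at 2 ms substeps (five per control interval), torque clamped to the
limit before integration, joint limits enforced by clamping the angle and
zeroing the limit-directed velocity.  The symplectic integrator's energy
error is a bounded shadow oscillation: <0.1% of total mechanical energy per
second on a locked-joint pendulum, ~0.4% of the swing amplitude.

The home pose is solved once per model by damped-least-squares inverse
kinematics from a fixed seed pose (mid-range null-space bias, then an
undamped polish), cached, and reused for every episode.  For the shorter
and longer arm variants the home position is scaled by the ratio of total
arm lengths, keeping the target geometry proportionate.

## Experts

**PPO policies** (the study protocol): two-hidden-layer tanh networks
(256 units each) mapping the observation to 7 torque means with
state-independent log standard deviations (initial std 0.5 N m); a critic
of the same trunk (separate parameters).  Training uses 3000 epochs of
10 000 steps, γ = 0.99, GAE λ = 0.97, clip ratio 0.2, learning rates
3e−4/1e−3, and 80 minibatch gradient steps per epoch for each network over
the epoch's shuffled data.  Observations are normalized by running
mean/variance (the raw radian/metre/unitless scales differ by orders of
magnitude); advantages are standardized per batch; the fixed horizon means
terminal bootstrap values are zero.  No entropy bonus or KL stopping by
default (both available).  Everything is plain numpy with manual
backpropagation and Adam — the implementation is self-contained.

**Surrogate experts** (the desk protocol): a no-training stand-in that
emulates the learned policies' competence.  The reach is planned as a
joint-space minimum-jerk motion s(τ) = 10τ³ − 15τ⁴ + 6τ⁵ from the home
pose to the inverse-kinematics pose of the target over [0, t_target], and
back over [t_target, t_finish] (stationary reversal, consistent with the
velocity penalty at the checkpoint).  Torques are inverse dynamics along
the reference plus PD feedback whose gains are specified per unit inertia
and scaled by the mass-matrix diagonal at the home pose — uniform gains are
discretely unstable at the 10 ms control rate on the low-inertia wrist.
Joint-space (not task-space) planning avoids Jacobian inversion near
singularities; the resulting fingertip paths are nevertheless nearly
straight (< 2 cm chord deviation), matching the qualitative character of
the learned policies.  Checkpoint errors are ~0.03 cm.

## Synergy extraction

A trial's signed T×M torque sequence is split into nonnegative positive and
negative parts, a⁺ = max(a, 0), a⁻ = −min(a, 0) (so a = a⁺ − a⁻), and
stacked into one 2MT-row column (all samples of a⁺ in time-major order,
then a⁻).  N trials form the action matrix X (2MT × N = 1400 × 8 here),
factorized as X ≈ WH with W ≥ 0 (2MT × L synergies) and H ≥ 0 (L × N
activations).

NMF uses Lee–Seung multiplicative updates for the squared Frobenius error:
max 5000 iterations, relative-improvement tolerance 1e−6, best of 10 random
nonnegative restarts, deterministic given a seed.  The scale indeterminacy
is resolved by normalizing W's columns to unit Euclidean norm (H rescaled),
and columns are ordered by descending total activation for stable indexing.
Extraction data are the deterministic (mean-action) rollouts, one per
training target (N = 8 per repertoire).

Reconstruction is scored by R² = 1 − SS_res/SS_tot on the *signed* trials,
pooled over all trials of a repertoire (the grand mean action is the
reference); per-trial R² is also exposed, and with N = 8 the two differ
little.  Held-out trials are projected onto a repertoire by nonnegative
least squares.

## Generalization

Member repertoires are column-concatenated, W′ = [W_h W_s],
L′ = L_h + L_s.  CMA-ES (standard rank-μ update with cumulative step-size
adaptation) searches R^{L′}; a candidate x becomes nonnegative activations
h′ = |x|, decoded to an open-loop torque sequence by unstacking W′h′ and
subtracting the negative block.  Each candidate is scored by the
accumulated reward G of one full open-loop episode (feed-forward control,
no feedback terms); diverged episodes score −∞ and are logged, not fatal.
Population size is 4 + ⌊3 ln L′⌋ (natural log, the cited strategy's
convention; 10 for L′ = 9), initial mean zero.  Each target is optimized
independently; per-target seeds derive deterministically from the master
seed.

The paper-profile initial step size is σ = 1e−3 with 500 generations.  The
desk profile uses 200 generations with σ = 0.3: under unit-norm W columns
the optimal activations are O(1–5), and 1e−3 spends most of a short budget
growing the step size (the usual guideline is roughly a third of the
typical scale; results are insensitive across 0.15–0.5).

## Scale profiles and what they show

- **paper**: PPO experts at the full budget, 500 generations, σ = 1e−3 —
  the study protocol; hours of CPU via the `synreach` CLI.
- **desk**: surrogate experts, 200 generations, σ = 0.3 — minutes; the
  default for tests and the acceptance script.
- **smoke**: 2 targets, 50 generations, CI-sized.

At desk scale the combination effect reproduces cleanly: single
repertoires of eight synergies reach the frontal targets with ~6.5 cm
(horizontal-derived) and ~8.8 cm (sagittal-derived) mean error, while the
combined 4+4 repertoire reaches ~2.4 ± 1.0 cm — roughly 0.4× the best
single repertoire.  The CMA-ES runs are fully converged (200 vs 1000
generations indistinguishable); the residual error is the intrinsic
open-loop composability frontier of a surrogate-derived basis at
L_h = L_s = 4, which tightens as the basis grows (~1.7 cm at 8+8).

The surrogate emulates the experts' *task-level competence* (accurate,
straight, reciprocating reaches), not the torque style of
feedback-trained policies, whose richer waveforms may compose better.
Desk-scale results therefore demonstrate the pipeline's mechanics and the
combination effect's direction and rough magnitude — not the sub-centimetre
combined accuracy of the full protocol.

## Numerical choices and degenerate inputs

- NMF rank is bounded by the trial count (L ≤ N); L > N is rejected.
- R² is undefined (raises) when the total sum of squares is zero.
- Non-finite observations, torques or candidates raise invalid-argument
  errors; integrator divergence (velocity norm > 1e6 rad/s) raises an error
  carrying the partial trajectory.
- The per-target CMA-ES seed schedule is `master + 1000003·k mod 2³¹`.
- All file containers are arrays (.npz) with JSON sidecars; trajectories
  also export to tidy CSV (one row per trial × sample), which is the entry
  point for external signed channel × time × trial data.

## Known limitations

- The arm's dynamic parameters (masses, damping, armature, torque limit)
  are modelling choices constrained only by qualitative behaviour; absolute
  torque magnitudes are not comparable to human or engine-specific values.
- Open-loop decoding is inherently sensitive to reconstruction error; the
  damping value partly controls this and is a declared model parameter, not
  a fitted one.
- Only joint-level (not muscle-level) synergies, fixed waveforms (no
  post-extraction synergy adaptation), no sensory feedback during decoded
  movements, no contact or obstacles.
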