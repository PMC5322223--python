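# Methods

## Overview

The package simulates a performer who executes two-step sequential hand
actions (reach-and-pour vs reach-and-move) and an observer who infers the
distal intention from noisy kinematics by probabilistic motor simulation.
Everything is synthetic and seeded; no human data enter the pipeline.

## Motor primitives

A primitive is a time-indexed diagonal Gaussian over J joint-angle channels,
`p(x_t|m) = N(mu_m(t), diag(sigma_m^2(t)))`, sampled at Δt = 10 ms
(151 frames over the 1500 ms sequence — fine enough to resolve the 500 ms
coarticulation window at negligible cost). Angles are flexion in radians
(0 = fully extended); time is in ms. The 16 channels are grouped
4 index / 4 thumb / 2 wrist / 6 other fingers; the grouping is configuration
(`channel_map`), since only the group semantics matter to the model.

Mean profiles are minimum-jerk interpolations between configured start and
end postures. The reach additionally carries a Gaussian-shaped *aperture
bump* (default 0.20 rad, centred at 750 ms, width 100 ms) on index and thumb:
the hand opens mid-reach and closes onto the grasp, producing a maximum grip
aperture (MGA) inside the reach phase, as in real prehension. Variance
profiles are smooth and strictly positive: the reach's per-channel SD rises
sinusoidally from 0.05 rad at the endpoints to 0.08 rad mid-movement
(mid-trajectory variability); the distal primitives' SD falls linearly from
0.12 rad at grasp onset to 0.04 rad at the end — the grasp-type constraint is
loose on approach and tightens toward contact. These SDs are chosen once as
plausible trial-to-trial variability for digit flexion; no published numeric
postures or variances exist for this scenario, so all posture values are
package configuration.

Default postures (radians of flexion, index/thumb group values):
relaxed start 0.95 → neutral grasp 0.75 for the reach; grasp-to-pour (power
grasp, wide) starts at 0.55 and ends at 0.50; grasp-to-move (precision grip,
narrow) starts at 0.95 and ends at 1.00. The two grasp types are deliberately
symmetric (±0.20 at onset, ±0.25 at the end) about the neutral grasp so the
two intentions are statistically exchangeable. Wrist and other-finger
channels are identical across the two distal primitives. The grasp-type
offset means plain-mode composition has a ≤0.20 rad index/thumb mean step at
the 1000 ms junction — the hand configuration snaps to the selected grasp at
contact; wrist/other channels are continuous there. This is intentional: a
grasp type that is *already* expressed at contact is what gives the observer
anything to read after the boundary, and (via the onset-clamped blend below)
what coarticulation leaks before it.

The emulated recording campaign (6 participants × 50 trials) is modelled as
i.i.d. trials; per-participant offsets are not modelled because no
between-subject variance is available to calibrate them, and nothing
downstream consumes participant identity.

## Coarticulation and signaling

At sequence time t inside the window (default 500–1000 ms), masked channels
(index+thumb) are drawn from the product density
`p_coa ∝ w_i p(x|m_i) ∏_j w_j p(x|m_j)` by rejection: propose from the
primary (reach) density and accept iff `u_j < w_j p(x̂|m_j)/p_j^max` for all
future primitives j, with u_j ~ U(0,1) and p^max the analytic per-channel
Gaussian supremum. Numerical choices:

- **Onset clamp.** A distal primitive queried before its nominal start is
  evaluated at its onset distribution. The blend therefore pulls the reach
  toward the *initial posture requirement* of the upcoming grasp, which is
  the behaviourally meaningful target during the reach.
- **Per-channel acceptance.** With diagonal covariance, the joint acceptance
  factorizes channel-wise; channels are accepted independently, which leaves
  the accepted joint law unchanged and keeps expected tries per step small.
  `RejectionExhaustedError` (default budget 10 000 rounds per step) signals
  near-disjoint primitives rather than looping silently.
- **Weights.** `w_j = 0` removes factor j (continuous identity limit). For
  `w_j ∈ (0, 1]` the linear weight scales acceptance uniformly, so the
  *normalized* accepted distribution is invariant in w on that interval;
  weights matter for the signaling density (below) and for acceptance cost.
- **Unmasked channels** always follow the primary primitive: wrist kinematics
  are coarticulation-free by construction.

Signaling uses the complementary acceptance `u_j < 1 − w_j p(x̂|m_j)/p_j^max`,
giving a density `∝ p(x|m_i) ∏ (1 − w_j p(x|m_j)/p_j^max)` that pushes
samples away from the future primitive. This dissimilation density is a
stated stand-in for a formal treatment that is not available; it has the
defining qualitative properties (opposite displacement to coarticulation,
identity at w = 0, mirror antisymmetry) and is exercised by tests only at
that qualitative level.

The closed-form product-of-Gaussians (`product_gaussian_oracle`: precisions
add, means precision-weighted) serves as the independent oracle for the
sampler in tests, and as the observer's closed-form description of
coarticulated frames.

## Performer

Frames are sampled independently per time step from the generating
distribution of the moment (reach, blended, or distal). Trajectory-coherent
sampling (e.g. one latent execution-noise draw per trial) would be the main
alternative; per-step sampling matches the per-instant probabilistic
interface of the densities above and makes every frame informative.
Observations add i.i.d. N(0, sigma_obs²) per channel, sigma_obs = 0.05 rad
by default (comparable to the execution SD, so the percept is noisy but not
dominated by sensor noise).

## Observer

Per hypothesis (candidate sequence, same repertoire and composition mode as
the performer — the shared-repertoire assumption), a Gaussian filter runs:

- predict: `u_t = mu_h(t) − mu_h(t−Δt)` (inverse model);
  `pred = N(belief + u_t, belief_var + q² + κ·sigma_h²(t))` with process
  noise q = 0.02 rad and execution-variance inflation κ = 1 (the forward
  model inherits the hypothesis's own execution variability);
- update: conjugate per-channel correction with the percept, returning the
  predictive log-likelihood `N(z_t; pred_mean, pred_var + sigma_obs²)`.

Log-likelihoods accumulate in log space with per-step renormalization
(underflow-safe); priors are uniform — a contextual prior p(i|c₀) is exposed
on `Hypothesis` but defaults to uninformative. The recognition time is the
first strict crossing of θ = 0.95; exact ties at θ do not cross, and a run
whose posterior never crosses is reported as undecided (batch summaries score
it at the sequence end). With q = 0 and κ = 0 the filters have zero gain and
the posterior reduces exactly to accumulated Gaussian likelihood ratios —
the configuration used for the closed-form equivalence test.

Because the two hypotheses share the reach primitive, plain-mode likelihoods
are *identical* before the boundary and the posterior is exactly 0.5 there;
recognition in plain mode therefore happens at the first post-boundary frame
(typically 1010 ms), while coarticulated-mode recognition typically happens
at the window opening (~500 ms), where the blended index/thumb distributions
of the two intentions first separate (by ≈0.1–0.12 rad per channel under
defaults).

## Experiments

`recognition_experiment` runs the 2 (intent) × 2 (mode) grid, 50 runs per
cell by default (matching the per-primitive trial count of the emulated
recordings at desk-scale runtime, ~10 s total), with per-run seeds spawned
deterministically from the master seed. It emits mean ± SD posterior curves,
per-run crossing times and medians, and the grip-aperture table.

Grip aperture is the configured linear functional
`theta_max − mean(flexion over index+thumb channels)` (theta_max = π/2): zero
at full flexion, maximal at full extension, monotone decreasing in every
digit flexion channel. MGA/tMGA are taken over the reach phase only
(t < 1000 ms), earliest-maximum tie rule. Group contrasts use two-sided
permutation tests on group means (10 000 seeded permutations) —
assumption-light and exactly reproducible; the implementation is verified
against `scipy.stats.permutation_test` in the test suite. Under defaults the
pour-vs-move MGA contrast is large (≈0.10 rad, p ≈ 1e-4 at n = 50/group);
the plain-vs-pour MGA contrast is small because the power-grasp onset sits
near the reach's own aperture peak — the ordering of conditions is
configuration-dependent and not asserted as a model property. tMGA contrasts
are weaker under defaults (all conditions peak near the bump centre).

`ExperimentSummary.save` writes CSV/JSON artifacts including the full config
and seed; `verify_results` reruns the experiment from those and compares all
artifacts byte-for-byte.

## What the synthetic generator does and does not emulate

It emulates: the channel grouping and timeline of multi-channel dataglove
recordings; reach-phase grip-aperture dynamics; grasp-type-specific hand
postures; trial-to-trial execution variability; observation noise. It does
not emulate: between-participant differences, within-trial autocorrelated
noise, arm transport/Cartesian kinematics, object contact, sensor
miscalibration, or non-Gaussian variability. Passing tests therefore show
that the coarticulation → early-recognition effect follows from the model's
probabilistic structure under realistic-scale parameters — not that the
effect sizes match any particular human dataset.

## Known limitations

- Diagonal covariance throughout; cross-channel correlation (strong in real
  hands) is not modelled, which likely overstates the observer's effective
  evidence per frame.
- The observer keys mostly on mean-profile differences at distribution
  change-points (window opening, grasp boundary); with constant mean offsets
  and high filter gain, evidence accumulation between change-points is slow.
- The signaling density is a stand-in (see above) and is not used by the
  batch experiments.
- Recognition times are reported on the 10 ms simulation grid.
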