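# coartsim

Simulation of **coarticulated sequential grasping** and **Bayesian intention
recognition**. A performer agent executes a two-step hand action — reach a
bottle, then either pour from it or move it — and an observer agent must infer
the distal intention (pour vs move) from noisy joint-angle kinematics as early
as possible. The package tests, in silico, the hypothesis that *coarticulation*
(shaping the reach so it also anticipates the upcoming grasp) is sufficient to
make the intention legible **before** the hand ever reaches the bottle.

## Who it is for

Researchers in computational motor control, social cognition and human-robot
interaction who want a fully synthetic, seeded, end-to-end testbed for
kinematic intention-reading: primitive libraries, coarticulated trajectory
generation, a multi-hypothesis Bayesian observer, and batch analyses of grip
aperture and recognition time.

## The model

**Motor primitives.** Each primitive `m` is a time-indexed diagonal Gaussian
over J = 16 joint-angle channels (index, thumb, wrist, other fingers; radians
of flexion): `p(x_t | m) = N(mu_m(t), diag(sigma_m^2(t)))`. The default
library has reach-to-grasp (0–1000 ms) plus grasp-to-pour (power grasp) and
grasp-to-move (precision grip) for the final 500 ms.

**Coarticulation.** During the 500–1000 ms window, index and thumb channels of
the reach are drawn by rejection sampling from the product density

```
p_coa(x | m_i; w)  ∝  w_i p(x|m_i) · ∏_{j≠i} w_j p(x|m_j)
```

a candidate `x̂ ~ p(x|m_i)` is accepted iff `u_j < w_j p(x̂|m_j)/p_j^max` for
every upcoming primitive `j` (with `u_j ~ U(0,1)`). The converse *signaling*
distribution, `∝ p(x|m_i) ∏ (1 − w_j p(x|m_j)/p_j^max)`, exaggerates the
differences instead.

**Observer.** One Gaussian (Kalman-style) filter per candidate sequence,
coupled inverse model (control = the hypothesis's mean kinematic increment)
and forward model, corrected by the noisy percepts `z_t = x_t + ε`. Per-frame
predictive log-likelihoods accumulate into the model posterior
`p(i_t | z_1:t)`; the first hypothesis to strictly exceed the decision
threshold θ = 0.95 is the recognized intention, and that instant is the
*crossing (recognition) time*.

## Worked example

```bash
coartsim experiment --runs 50 --seed 7 --out results/
```

prints

```
move_coarticulated: median crossing 500 ms
move_plain: median crossing 1010 ms
pour_coarticulated: median crossing 500 ms
pour_plain: median crossing 1010 ms
wrote artifacts to results/
```

Without coarticulation the observer cannot tell pour from move until the hand
is on the bottle — the posterior first clears θ at 1010 ms, one time step
after the 1000 ms reach/grasp boundary (before it, both hypotheses share the
reach primitive and the posterior sits at exactly 0.5). With coarticulation
the intention is read at the opening of the 500 ms coarticulation window,
500 ms before the grasp. The output directory also contains per-cell
mean ± SD posterior curves, per-run crossing times, and the grip-aperture
table: under the default conditions the maximum grip aperture (MGA) during
the reach averages 1.03 rad when coarticulating with pour (power grasp) vs
0.93 rad with move (precision grip), a contrast with permutation
p ≈ 1e-4 at 50 trials/group — the kinematic signature that makes early
reading possible. `coartsim verify results/` recomputes every artifact from
the recorded config and seed and checks them byte-for-byte.

Single trials and recognitions are available as
`coartsim simulate --intent pour --mode coarticulated --seed 3 --out trial.csv --observe`
followed by `coartsim recognize --trial trial.csv --out posterior.csv`, or
programmatically via `compose_sequence`, `observe` and `IntentionObserver`.

## Layout

- `src/coartsim/primitives.py` — primitive library, trial simulator, and the
  `GaussianTrajectoryRegressor` estimator (kernel-smoothed per-bin fits)
- `src/coartsim/coarticulation.py` — product/signaling densities, rejection
  samplers, closed-form product-of-Gaussians oracle
- `src/coartsim/performer.py` — sequence composition and noisy observation
- `src/coartsim/observer.py` — multi-hypothesis filter and the
  `IntentionObserver` estimator
- `src/coartsim/experiments.py` — MGA analysis, permutation tests, the 2×2
  batch experiment, artifact verification
- `configs/default.yaml` — the full default configuration
- `docs/methods.md` — modelling assumptions, parameter choices, limitations
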