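channels: 16
dt_ms: 10.0
channel_map:
  index:
  - 0
  - 1
  - 2
  - 3
  thumb:
  - 4
  - 5
  - 6
  - 7
  wrist:
  - 8
  - 9
  other:
  - 10
  - 11
  - 12
  - 13
  - 14
  - 15
timeline:
  reach_end_ms: 1000.0
  sequence_end_ms: 1500.0
primitives:
  reach_to_grasp:
    role: proximal
    start_posture:
      index: 0.95
      thumb: 0.95
      wrist: 0.1
      other: 0.95
    end_posture:
      index: 0.75
      thumb: 0.75
      wrist: 0.2
      other: 0.8
    aperture_bump:
      amplitude: 0.2
      center_ms: 750.0
      width_ms: 100.0
      groups:
      - index
      - thumb
    variance_profile:
      kind: sine
      base_sd: 0.05
      peak_sd: 0.08
  grasp_to_pour:
    role: distal
    start_posture:
      index: 0.55
      thumb: 0.55
      wrist: 0.2
      other: 0.7
    end_posture:
      index: 0.5
      thumb: 0.5
      wrist: 0.3
      other: 0.65
    variance_profile:
      kind: linear
      start_sd: 0.12
      end_sd: 0.04
  grasp_to_move:
    role: distal
    start_posture:
      index: 0.95
      thumb: 0.95
      wrist: 0.2
      other: 0.7
    end_posture:
      index: 1.0
      thumb: 1.0
      wrist: 0.3
      other: 0.65
    variance_profile:
      kind: linear
      start_sd: 0.12
      end_sd: 0.04
coarticulation:
  window_ms:
  - 500.0
  - 1000.0
  weights:
    reach_to_grasp: 1.0
    grasp_to_pour: 1.0
    grasp_to_move: 1.0
  dof_groups:
  - index
  - thumb
  max_tries: 10000
observation:
  sigma_obs: 0.05
observer:
  threshold: 0.95
  process_noise: 0.02
  state_var_inflation: 1.0
experiment:
  n_runs: 50
  intents:
  - pour
  - move
  modes:
  - plain
  - coarticulated
mga:
  theta_max: 1.5707963267948966
  n_permutations: 10000
fit:
  smoothing_ms: 30.0
  var_floor: 1.0e-06
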