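# End-to-end demo study: 3 dose groups x 2 days, planted high-dose effect.
seed: 11
doses: [control, 100ug, 200ug]
days: [day1, day2]
n_fish_per_group: 10
trial_duration: 600.0     # s (10-min trials)
sample_rate: 25.0         # Hz

groups:
  control: {mean_speed: 6.0, speed_sd: 1.5, p_alternate: 0.55}
  100ug:   {mean_speed: 6.0, speed_sd: 1.5, p_alternate: 0.55}
  200ug:   {mean_speed: 3.0, speed_sd: 1.0, p_alternate: 0.2,
            freeze_rate: 3.0, freeze_duration: 4.0}

window_s: 30.0
image_size: 64
holdout_frac: 0.2
experiments: [E1, E2A, E2B, E3A, E3B]

train:
  arch: small_resnet
  epochs: 6
  lr: 0.003

permutation_reps: 1000
alpha: 0.05
louvain_restarts: 10

mortality:
  doses_ug: [0, 50, 100, 200, 400]
  n_per_group: [40, 40, 40, 40, 40]
  true_ld50: 292.0
  probit_slope: 2.0
  control_rate: 0.05

iat:
  control: {n: 19, learned_delta: 40.0, noise_sd: 10.0, nonavoider_rate: 0.1}
  200ug:   {n: 19, learned_delta: 0.0, noise_sd: 10.0, nonavoider_rate: 0.1}
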