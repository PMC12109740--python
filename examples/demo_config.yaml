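# End-to-end demo configuration for `photokv run`.
# Reproduces the torus tension worked values and runs every analysis stage
# on freshly simulated inputs.
seed: 1
stages: [tension, cm, profiles, single_channel, iv]

tension:
  r0_um: 29.5
  rin_um: 27.5
  sigma0_mN_per_m: 4.0
  eta_h_nNs_per_m: 500.0
  tau_ms: 23.0

cm:
  c_base_pF: 80.0
  dc_frac: -0.06
  tau_relax_ms: 23.0
  noise_sd_pF: 0.05
  t_on_ms: 100.0
  duration_ms: 500.0

profiles:
  frame_ms: 40.0
  noise_sd: 0.02
  n_frames: 8
  switch_frame: 3

single_channel:
  n_channels: 3
  p_open_cis: 0.05
  p_open_trans: 0.30
  voltage_mV: 120.0
  duration_ms: 3000.0

iv:
  v_half_cis_mV: 158.6
  v_half_trans_mV: 120.9
  v_s_mV: 15.0
  g_max_nS: 2.0
  noise_sd_pA: 5.0
  n_replicates: 5
  mode: steady
  v_test_mV: 120.0
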