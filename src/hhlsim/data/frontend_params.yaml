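middle_ear:
  f_lo_hz: 12500.0
  f_hi_hz: 22000.0
  order: 2
  stapes_gain: 1.0
drnl:
  bw_factor: 0.09
  bw_min_hz: 300.0
  lin_gain: 0.001
  lin_bw_factor: 1.3
  nl_order: 3
  nl_a: 1.0
  nl_b: 0.00042
  nl_c: 0.2
ihc:
  tau_c_ms: 2.13
  cilia_gain: 11007295.535692597
  g_cilia_max_nS: 8.0
  g_a_nS: 0.33
  u0_nm: 7.0
  s0_nm: 85.0
  u1_nm: 7.0
  s1_nm: 5.0
  c_m_pF: 6.0
  g_k_nS: 27.1
  e_t_mV: 100.0
  e_k_mV: -70.45
  rp_over_rp_rt: 0.04
  tau_m_ca_ms: 0.1
  beta_ca: 400.0
  gamma_ca_per_mV: 0.13
  e_ca_mV: 66.0
  tau_ca_ms: 0.1
pools:
  M: 10
  x: 66.31
  y: 10.0
  l: 2580.0
  r: 6580.0
types:
  LT:
    g_ca_max_nS: 4.0
    ca_thr: 0.0
    n_lin: 3
  MT:
    g_ca_max_nS: 3.0
    ca_thr: 0.10129080777056014
    n_lin: 3
  HT:
    g_ca_max_nS: 2.0
    ca_thr: 0.06972968770651354
    n_lin: 1
z: 715.1392997570846
n_channels: 21
f_min_hz: 5600.0
f_max_hz: 32000.0
release_model: pools
s1_threshold_mod: false
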