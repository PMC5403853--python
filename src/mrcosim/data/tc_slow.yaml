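engine:
  t_end: 2.0
  strategy: fast-first
  communication: asynchronous
  mode: multirate
models:
  problem: testcase
  variant: TC-slow
  rel_tol: 1.0e-05
  electrical:
    soma_diameter: 20.0
    dend_diameter: 3.0
    dend_length: 25.0
    n_dend: 15
    spine_area_um2: 1.0
    axial_resistivity: 150.0
    spine_neck_radius_um: 0.05
    spine_neck_length_um: 1.0
    cm_uf_per_cm2: 1.0
    g_leak_s_per_cm2: 2.05e-05
    e_leak: -70.3
    g_na_s_per_cm2: 0.056
    g_kd_s_per_cm2: 0.006
    g_m_s_per_cm2: 7.5e-05
    e_na: 50.0
    e_k: -90.0
    v_t: -56.2
    tau_max_adapt: 0.608
    g_k_spine: 0.002
    g_ca_spine: 0.0005
    e_ca: 120.0
    tau_m_ca: 0.0003
    v_half_ca: -35.0
    k_ca_slope: 7.0
    ca_rest: 0.08
    tau_ca: 0.1
    ca_per_na: 40000.0
    u_rest: 1.0
  biochemical:
    a_total: 1.0
    m_total: 1.0
    k_total: 1.0
    k_act: 0.3
    k_ca_half: 0.35
    hill: 4.0
    k_fb: 0.4
    k_fb_half: 0.3
    k_inact: 0.1
    k_cat: 0.3
    km_phos: 0.1
    v_dephos: 0.1
    km_dephos: 0.1
    k_channel_p: 0.2
    k_channel_d: 0.1
    ca_rest: 0.08
    tau_ca: 0.1
    c1: 1.0
  protocol:
    t_total: 5.0
    burst_start: 4.0
    pulse_rate: 2.0
    pulse_onset: 0.05
    pulse_width: 0.005
    pulse_amplitude: 0.35
    burst_amplitude: 0.15
    baseline: 0.0
coupling:
  c1: 1.0
sweep:
  tolerances:
  - 1.0e-05
  - 1.0e-06
  - 1.0e-07
  observables:
  - V
  - Ca
  - K_A
  - P_MAPK
  t_eval: 2.0
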