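# Default archetype and synapse calibration (version 1).
#
# Group passive statistics are the published group means; dispersions are
# SEM * sqrt(n) from the same source, with the coefficient of variation
# capped at 0.5 so that sampled cells stay within the regime where the
# single-compartment model is well behaved (see docs/methods.md).
# Conductances in nS, capacitance in pF, voltages in mV, times in ms
# unless suffixed otherwise.
#
# Calibration targets: group means for capacitance / input resistance /
# resting potential / rheobase; the leak-subtracted I_h amplitudes at
# voltage steps of -30/-60/-90 mV (-118/-408/-616 pA); a rebound-firing
# threshold near -140 mV abolished by HCN block; the firing-type
# batteries (tonic stable with <=109 spikes at 500 pA, fading with
# amplitude decline + mid-step failure, single with <3 APs everywhere);
# and the evoked-input latency / jitter / failure / depression values.
version: 1

groups:
  CC:
    passive:
      Cm_pF:    {mean: 138.1,  sd: 0.66,  dist: normal}
      Rm_GOhm:  {mean: 0.41,   sd: 0.205, dist: lognormal}
      Vrest_mV: {mean: -58.91, sd: 8.46,  dist: normal}
    rheobase_target_pA: 81.8
    g_h_nS: 4.2
    g_KLT_nS: 20.0
    klt_tau_ms: 15.0          # slow KLT: lags the rebound ramp
    default_kind: T
    mixture: {T: 0.56, F: 0.32, S: 0.12, U: 0.0}
    n_cc_hyperpol_steps: 10
    kind_overrides:
      F: {slow_depth: 0.92, slow_tau_ms: 160.0, slow_Vhalf_mV: -51.0}
  medial:
    passive:
      Cm_pF:    {mean: 19.35,  sd: 9.35,  dist: lognormal}
      Rm_GOhm:  {mean: 1.81,   sd: 0.905, dist: lognormal}
      Vrest_mV: {mean: -53.75, sd: 4.80,  dist: normal}
    rheobase_target_pA: 32.6
    g_h_nS: 0.0
    g_KLT_nS: 5.0
    k_shift_mV: 5.0
    default_kind: F
    mixture: {T: 0.222, F: 0.519, S: 0.185, U: 0.074}
    n_cc_hyperpol_steps: 4
    kind_overrides:
      T: {k_tau_scale: 2.0}   # slower Kv kinetics: lower peak rates
      F: {slow_depth: 0.95, slow_tau_ms: 100.0, slow_Vhalf_mV: -57.0}
  lateral:
    passive:
      Cm_pF:    {mean: 30.9,   sd: 15.45, dist: lognormal}
      Rm_GOhm:  {mean: 0.99,   sd: 0.495, dist: lognormal}
      Vrest_mV: {mean: -51.9,  sd: 9.26,  dist: normal}
    rheobase_target_pA: 68.15
    g_h_nS: 0.0
    g_KLT_nS: 13.0
    k_shift_mV: 5.0
    default_kind: F
    mixture: {T: 0.154, F: 0.577, S: 0.192, U: 0.077}
    n_cc_hyperpol_steps: 6
    kind_overrides:
      T: {k_tau_scale: 2.0}
      F: {slow_depth: 0.90, slow_tau_ms: 120.0, slow_Vhalf_mV: -52.0}

# Firing archetypes: the slow Na-inactivation variable differs per kind.
# Tonic cells barely inactivate; fading cells accumulate inactivation over
# ~100 ms leading to amplitude decline, failure and a depolarized baseline;
# single cells inactivate so fast and deeply that firing stops after 1-2
# APs; undefined cells sit near the tonic/fading boundary.
archetype_kinds:
  T: {slow_depth: 0.05, slow_tau_ms: 500.0}
  F: {slow_depth: 0.80, slow_tau_ms: 150.0, slow_Vhalf_mV: -48.0, slow_k_mV: 6.0}
  S: {slow_depth: 0.997, slow_tau_ms: 4.0, slow_Vhalf_mV: -63.0, slow_k_mV: 3.0,
      g_Na_scale: 0.8}
  U: {slow_depth: 0.50, slow_tau_ms: 300.0, slow_Vhalf_mV: -48.0, slow_k_mV: 6.0}

# Spike-current densities (scaled by cell capacitance) and activation
# shifts that position spike threshold near -50 mV.
densities:
  g_Na_nS_per_pF: 35.0
  g_K_nS_per_pF: 15.0
shifts:
  na_shift_mV: 6.0
  k_shift_mV: 7.0

# Low-threshold K conductance: sets rheobase above the bare (V_thr -
# V_rest)/R_m prediction without adding a slow adaptation that would
# fade spike amplitudes.
klt:
  Vhalf_mV: -43.0
  k_mV: 4.0
  tau_ms: 5.0

# First-order HCN gate: calibrated so leak-subtracted I_h at voltage-clamp
# steps of -30/-60/-90 mV from -70 mV holding reproduces the published
# -118/-408/-616 pA for the Clarke's column archetype, and residual I_h
# after deep hyperpolarizing current steps drives rebound firing with a
# threshold near -140 mV.
hcn:
  Vhalf_mV: -100.0
  k_mV: 10.0
  tau0_ms: 30.0
  tau_amp_ms: 450.0
  tau_Vhalf_mV: -120.0
  tau_k_mV: 20.0
  E_h_mV: -30.0

noise:
  cc_sigma_mV: 0.4     # membrane-potential SD in current clamp
  vc_sd_pA: 4.0        # recording noise added to voltage-clamp traces

# Synaptic-input presets. Latency/jitter/failure/depression values are the
# published per-condition statistics; optogenetic latencies are apparent
# latencies (they include the ~6 ms shutter-opening lag).
synapses:
  cc_electrical_mono:       # distal dorsal-root single-EPSC input to CC
    latency_mean_ms: 5.6
    latency_sd_ms: 0.13
    release_prob: 0.991
    quantal_amp_pA: 415.3
    rise_ms: 0.5
    decay_ms: 6.0
    depression_U: 0.5
    tau_rec_s: 0.247
    amp_cv: 0.2
    stim_modality: electrical
  cc_electrical_local:
    latency_mean_ms: 2.5
    latency_sd_ms: 0.13
    release_prob: 0.991
    quantal_amp_pA: 534.1
    rise_ms: 0.5
    decay_ms: 6.0
    depression_U: 0.5
    tau_rec_s: 0.247
    amp_cv: 0.2
    stim_modality: electrical
  medial_opto_mono:
    latency_mean_ms: 13.5
    latency_sd_ms: 0.35
    release_prob: 0.95
    quantal_amp_pA: 120.0
    rise_ms: 0.6
    decay_ms: 7.0
    amp_cv: 0.25
    stim_modality: optogenetic
  lateral_opto_mono:
    latency_mean_ms: 14.0
    latency_sd_ms: 0.74
    release_prob: 0.95
    quantal_amp_pA: 110.0
    rise_ms: 0.6
    decay_ms: 7.0
    amp_cv: 0.25
    stim_modality: optogenetic
  polysynaptic_electrical:
    latency_mean_ms: 12.0
    latency_sd_ms: 36.5
    release_prob: 0.8
    quantal_amp_pA: 90.0
    rise_ms: 0.8
    decay_ms: 8.0
    amp_cv: 0.3
    polysynaptic: true
    poly_offset_ms: 6.0
    stim_modality: electrical
  barrage:
    latency_mean_ms: 6.0
    latency_sd_ms: 0.5
    release_prob: 0.0       # no direct monosynaptic component
    quantal_amp_pA: 0.0
    barrage_n_mean: 6.0
    barrage_tau_ms: 150.0
    barrage_amp_pA: 60.0
    stim_modality: electrical

# Optogenetic shutter mechanics: the electronic trigger precedes light
# onset by the shutter-opening latency, so apparent latency = shutter lag
# plus synaptic latency. Included in the preset latency means above.
optogenetics:
  shutter_latency_ms: 6.0
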