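{
 "membrane": {
  "dIN": {
   "C_pF": 10.0,
   "gL_nS": 3.0,
   "EL_mV": -51.0,
   "gNa_nS": 1200.0,
   "ENa_mV": 50.0,
   "gK_nS": 360.0,
   "EK_mV": -77.0,
   "g_adapt_nS": 53.68700475,
   "tau_adapt_ms": 29.36935678,
   "b_adapt": 1.1054945,
   "threshold_mV": 0.0
  },
  "MN": {
   "C_pF": 10.0,
   "gL_nS": 3.0,
   "EL_mV": -54.4,
   "gNa_nS": 1200.0,
   "ENa_mV": 50.0,
   "gK_nS": 360.0,
   "EK_mV": -77.0,
   "g_adapt_nS": 0.0,
   "tau_adapt_ms": 100.0,
   "b_adapt": 0.0,
   "threshold_mV": 0.0
  },
  "vest_spin": {
   "C_pF": 10.0,
   "gL_nS": 3.0,
   "EL_mV": -54.4,
   "gNa_nS": 1200.0,
   "ENa_mV": 50.0,
   "gK_nS": 360.0,
   "EK_mV": -77.0,
   "g_adapt_nS": 0.0,
   "tau_adapt_ms": 100.0,
   "b_adapt": 0.0,
   "threshold_mV": 0.0
  }
 },
 "synapses": {
  "din_cin_ampa_nS": 8.0,
  "din_spmn_ampa_nS": 6.0,
  "din_self_ampa_nS": 0.39227828,
  "din_self_nmda_nS": 5.80906148,
  "cin_cin_inh_nS": 10.0,
  "cin_din_inh_nS": 25.0,
  "cin_spmn_inh_nS": 20.0,
  "spmn_ec_ampa_nS": 2.2,
  "ec_abd_ampa_nS": 2.0,
  "vo_abd_ampa_nS": 2.0,
  "vs_spmn_ampa_nS": 0.05,
  "vs_ec_ampa_nS": 0.3,
  "tau_rise_ampa_ms": 0.2,
  "tau_decay_ampa_ms": 3.0,
  "tau_rise_nmda_ms": 5.0,
  "tau_decay_nmda_ms": 80.0,
  "tau_rise_inh_ms": 1.5,
  "tau_decay_inh_ms": 12.75218667,
  "E_exc_mV": 0.0,
  "E_inh_mV": -75.0,
  "delay_ms": 1.0,
  "tau_rise_drive_ms": 0.5,
  "tau_decay_drive_ms": 25.0,
  "tau_decay_inh_spmn_ms": 40.0
 },
 "gating": {
  "iTrans_nA": 0.16,
  "sigmAmp": 1.0,
  "sigmSteep_per_nA": 200.0,
  "num_syn_inh": 10,
  "unitary_gGABA_nS": 1.0,
  "event_rate_hz": 10.0,
  "tau1_ms": 0.5,
  "tau2_ms": 100.0
 }
}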