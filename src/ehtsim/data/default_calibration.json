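{
 "regions": {
  "BZ": {
   "apd_target": 384.0,
   "automaticity_cl": null,
   "excitability_scale": 0.38,
   "region": "BZ",
   "resting_potential_offset": 0.0,
   "tau_close": 347.734375,
   "tau_in": 0.089609375,
   "tau_open": 80.0,
   "tau_out": 2.68828125,
   "u_gate": 0.13,
   "v_peak": 25.0,
   "v_rest": -85.0
  },
  "CS": {
   "apd_target": 310.0,
   "automaticity_cl": null,
   "excitability_scale": 1.0,
   "region": "CS",
   "resting_potential_offset": 3.0,
   "tau_close": 142.34375,
   "tau_in": 0.089609375,
   "tau_open": 80.0,
   "tau_out": 2.68828125,
   "u_gate": 0.13,
   "v_peak": 25.0,
   "v_rest": -85.0
  },
  "EHT": {
   "apd_target": 405.0,
   "automaticity_cl": null,
   "excitability_scale": 1.0,
   "region": "EHT",
   "resting_potential_offset": 0.0,
   "tau_close": 172.96668640136716,
   "tau_in": 0.34484375,
   "tau_open": 80.0,
   "tau_out": 10.3453125,
   "u_gate": 0.13,
   "v_peak": 25.0,
   "v_rest": -85.0
  },
  "HZ_ENDO": {
   "apd_target": 218.0,
   "automaticity_cl": null,
   "excitability_scale": 1.0,
   "region": "HZ_ENDO",
   "resting_potential_offset": 0.0,
   "tau_close": 97.01171875,
   "tau_in": 0.089609375,
   "tau_open": 80.0,
   "tau_out": 2.68828125,
   "u_gate": 0.13,
   "v_peak": 25.0,
   "v_rest": -85.0
  },
  "HZ_EPI": {
   "apd_target": 196.0,
   "automaticity_cl": null,
   "excitability_scale": 1.0,
   "region": "HZ_EPI",
   "resting_potential_offset": 0.0,
   "tau_close": 86.484375,
   "tau_in": 0.089609375,
   "tau_open": 80.0,
   "tau_out": 2.68828125,
   "u_gate": 0.13,
   "v_peak": 25.0,
   "v_rest": -85.0
  },
  "HZ_MID": {
   "apd_target": 207.0,
   "automaticity_cl": null,
   "excitability_scale": 1.0,
   "region": "HZ_MID",
   "resting_potential_offset": 0.0,
   "tau_close": 91.640625,
   "tau_in": 0.089609375,
   "tau_open": 80.0,
   "tau_out": 2.68828125,
   "u_gate": 0.13,
   "v_peak": 25.0,
   "v_rest": -85.0
  }
 }
}
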