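{
  "name": "dc_gater",
  "comment": "Single wt-like pore held at -160 mV; closes once at ~1/s into a gated state drawing a fresh conductance ratio from the truncated normal (mean 0.14, sd 0.05); no reopening at this bias.",
  "pore": "wt_like",
  "n_pores": 1,
  "rate_model": {"polarity": "negative", "critical_voltage": 0.10,
                 "closing_prefactor": 0.3, "closing_efold_voltage": 0.05,
                 "opening_rate": 0.0, "reopening_window": 0.02},
  "closed_state": {"mean_ratio": 0.14, "sd_ratio": 0.05},
  "protocol": {"kind": "constant", "amplitude": -0.16, "duration": 5.0,
               "sample_rate": 5000.0},
  "noise": {"relative_sd": 0.02},
  "seed": 1
}
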