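{
  "name": "wt_fig2c",
  "comment": "26 wt-like negative-gating pores under the 0.1 Hz / 200 mV sinusoid, 50 cycles: the ensemble hysteresis-loop experiment.",
  "pore": "wt_like",
  "n_pores": 26,
  "rate_model": {"polarity": "negative", "critical_voltage": 0.12,
                 "closing_prefactor": 2.0, "closing_efold_voltage": 0.04,
                 "opening_rate": 30.0, "reopening_window": 0.08},
  "closed_state": {"mean_ratio": 0.14, "sd_ratio": 0.05},
  "protocol": {"preset": "fig2c", "duration": 500.0},
  "noise": {"relative_sd": 0.01},
  "seed": 1
}
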