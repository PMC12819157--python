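{
  "name": "ergodicity",
  "comment": "Sharp negative gater for the time-average vs ensemble-average comparison: closing-time jitter (~20 ms) and reopening jitter (~12 ms) are both well inside the 1/64-cycle smoothing window (156 ms at 0.1 Hz).",
  "pore": "wt_like",
  "n_pores": 50,
  "rate_model": {"polarity": "negative", "critical_voltage": 0.12,
                 "closing_prefactor": 50.0, "closing_efold_voltage": 0.03,
                 "opening_rate": 80.0, "reopening_window": 0.05},
  "closed_state": {"mean_ratio": 0.14, "sd_ratio": 0.05},
  "protocol": {"preset": "fig2c", "duration": 10.0},
  "noise": {"relative_sd": 0.0},
  "seed": 1
}
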