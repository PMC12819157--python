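{
  "name": "neutral_fig2a",
  "comment": "6 neutral-lumen non-gating pores under the 2 Hz / 200 mV triangle: ohmic, hysteresis-free control.",
  "pore": "neutral",
  "n_pores": 6,
  "rate_model": {"polarity": "none", "critical_voltage": 0.1,
                 "closing_prefactor": 0.0, "closing_efold_voltage": 0.05,
                 "opening_rate": 0.0, "reopening_window": 0.02},
  "closed_state": {"mean_ratio": 0.14, "sd_ratio": 0.05},
  "protocol": {"preset": "fig2a", "duration": 5.0},
  "noise": {"relative_sd": 0.01},
  "seed": 1
}
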