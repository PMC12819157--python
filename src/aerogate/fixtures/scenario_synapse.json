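{
  "name": "synapse",
  "comment": "Strong negative gater (E254A-like) for the potentiation/depression pulse experiments: closes fast at -110 mV, reopens fast at +110 mV, inert at the -90 mV baseline. Pair with the fig6_potentiation / fig6_depression protocols.",
  "pore": "wt_like",
  "n_pores": 200,
  "rate_model": {"polarity": "negative", "critical_voltage": 0.10,
                 "closing_prefactor": 40.0, "closing_efold_voltage": 0.01,
                 "opening_rate": 60.0, "reopening_window": 0.05},
  "closed_state": {"mean_ratio": 0.14, "sd_ratio": 0.05},
  "protocol": {"preset": "fig6_potentiation"},
  "noise": {"relative_sd": 0.005},
  "initial_closed_fraction": 1.0,
  "seed": 1
}
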