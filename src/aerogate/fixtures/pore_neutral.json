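{
  "name": "neutral",
  "comment": "Neutral-lumen mutant: no ring charges; the IV curve is ohmic.",
  "geometry": {"radius_nm": 0.7, "length_nm": 10.0},
  "charges": [],
  "electrolyte": {"molar": 1.0, "temperature_K": 298.0,
                  "D_cation": 1.957e-9, "D_anion": 2.032e-9}
}
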