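{
  "name": "wt_like",
  "comment": "Heptameric aerolysin-like cylinder: positive ring near the cis mouth, negative rings mid-lumen and near the trans mouth; net negative charge toward trans gives beta < 0 (larger current magnitude at -100 mV).",
  "geometry": {"radius_nm": 0.7, "length_nm": 10.0},
  "charges": [
    {"z_nm": 2.0, "valence": 1, "multiplicity": 7},
    {"z_nm": 5.0, "valence": -1, "multiplicity": 7},
    {"z_nm": 8.5, "valence": -1, "multiplicity": 7}
  ],
  "electrolyte": {"molar": 1.0, "temperature_K": 298.0,
                  "D_cation": 1.957e-9, "D_anion": 2.032e-9}
}
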