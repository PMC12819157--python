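{
  "name": "single_ring",
  "comment": "A single negative heptameric ring at mid-pore (symmetric: beta = 0 up to the K+/Cl- diffusivity difference).",
  "geometry": {"radius_nm": 0.7, "length_nm": 10.0},
  "charges": [{"z_nm": 5.0, "valence": -1, "multiplicity": 7}],
  "electrolyte": {"molar": 1.0, "temperature_K": 298.0,
                  "D_cation": 1.957e-9, "D_anion": 2.032e-9}
}
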